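# ligmode

Trajectory analyses for characterizing how a ligand binds inside a buried
protein cavity:

- **dRMSD** pose comparison over ligand-to-binding-site internal distances
  (superposition-free), with the binding site frozen as every protein heavy
  atom within a cutoff (default 6 Å) of the ligand heavy atoms;
- **escape-time statistics**: per-replica ligand-RMSD series (global Cα
  prefit), first-passage time to a threshold (default 4 Å) with censoring,
  and rank-based medians/quartiles where censored replicas outrank all
  observed ones;
- **orientation maps**: polar collective variables (θ, φ) of the ligand
  hydroxyl-O → bridging-C vector in a common reference frame, binned with
  exact solid-angle reweighting (density per steradian,
  Σ density·Ω = 1);
- **water exchange**: hysteretic cavity occupancy per water, residence
  filtering of boundary flicker, entry/exit event extraction and
  nearest-gate channel assignment (A/B) with per-channel fractions;
- **GROMOS/Daura clustering** of ligand conformations (greedy
  most-neighbors extraction at an RMSD cutoff, default 2 Å) and projection
  of top cluster centroids onto the orientation map;
- **monitors**: minimum ligand–residue distances with a strict frame
  filter, salt-bridge distance/broken series, region RMSD after global fit;
- a **synthetic-data module** generating seedable toy complexes (spherical
  shell, two labelled channel cones with gate residues, rigid 5-atom
  ligand), von Mises–Fisher orientation mixtures with scheduled escapes,
  and scripted water-exchange trajectories with ground-truth records —
  so every stage is testable without MD.

I/O supports PDB/GRO structures and XTC/DCD/multi-model-PDB trajectories
(biotite and MDAnalysis under the hood), a small selection grammar
(`resname`, `resid` (with ranges), `name`, `chain`, `element`, `heavy`,
`water`, `protein`, boolean operators, and inclusive `within R of <sel>`),
and Kabsch superposition. Units: Å, ns; frame indices 0-based; residue
numbers as in the source file.

## CLI

```sh
ligmode run --out runs/demo --seed 1          # synthetic end-to-end pipeline
ligmode synth --out runs/s --seed 1           # toy complex + trajectory only
ligmode drmsd --reference ref.pdb --model model.pdb --ligand "resname LIG and heavy"
ligmode site-rmsd --struct-a a.pdb --struct-b b.pdb --site "protein and heavy and resid 207:211"
ligmode escape --manifest replicas.csv --out runs/escape
ligmode orient-map --topology top.pdb --trajectory t.xtc --out runs/orient
ligmode water --topology top.pdb --trajectory t.xtc --out runs/water
ligmode cluster --topology top.pdb --trajectory t.xtc --cutoff 2.0 --out runs/clu
ligmode monitor --topology top.pdb --trajectory t.xtc --residue "resid 247" --out runs/mon
```

`ligmode run` accepts a YAML config (`--config`, see
`ligmode.cli.PipelineConfig` for the keys); CLI flags override config
values. Every CSV output carries `#` provenance headers (version, config
hash, seed); reruns with the same config and seed are byte-identical.

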