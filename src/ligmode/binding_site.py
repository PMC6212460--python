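"""Binding-site definition, dRMSD pose comparison and monitor series.

The binding site is frozen on the reference coordinates: every protein
heavy atom within a cutoff (default 6 A) of any ligand heavy atom.  The
dRMSD compares the ligand-to-site distance matrices of two structures,

    dRMSD = sqrt( sum_i sum_j (d_ij^x - d_ij^m)^2 / N ),

where d_ij are ligand-atom-to-site-atom distances, x/m the two complexes
and N the number of (ligand, site) pairs.  Being built from internal
distances it needs no superposition and is invariant under rigid
transforms of either structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import StructureError, UsageError
from .trajio import (
    MolecularSystem,
    Selection,
    Trajectory,
    select,
    superpose,
    rmsd,
)

__all__ = [
    "BindingSiteDefinition",
    "SiteRMSDResult",
    "SaltBridgeSeries",
    "define_binding_site",
    "drmsd",
    "pairwise_site_rmsd",
    "min_residue_distance",
    "frames_below",
    "salt_bridge_series",
    "region_rmsd_series",
]


@dataclass
class BindingSiteDefinition:
    """Frozen ligand/site atom index sets plus the reference distances."""

    reference: MolecularSystem
    ligand_indices: np.ndarray   # ligand heavy atoms
    site_indices: np.ndarray     # protein (site) atoms
    cutoff: float
    reference_distances: np.ndarray  # (n_ligand, n_site)

    @property
    def n_pairs(self) -> int:
        return len(self.ligand_indices) * len(self.site_indices)


def define_binding_site(reference: MolecularSystem,
                        ligand_selection: Selection | np.ndarray,
                        cutoff: float = 6.0,
                        include_site_hydrogens: bool = False
                        ) -> BindingSiteDefinition:
    """Site atoms = non-ligand, non-water atoms within ``cutoff`` (inclusive)
    of any ligand heavy atom, on the reference coordinates.

    Heavy atoms only on both sides by default; the protein side can be
    opened to hydrogens with ``include_site_hydrogens``.
    """
    lig = np.asarray(getattr(ligand_selection, "indices", ligand_selection),
                     dtype=np.intp)
    if len(lig) == 0:
        raise UsageError("ligand selection is empty")
    heavy = reference.heavy_mask()
    lig_heavy = lig[heavy[lig]]
    if len(lig_heavy) == 0:
        raise UsageError("ligand selection contains no heavy atoms")

    candidate = np.ones(reference.n_atoms, dtype=bool)
    candidate[lig] = False
    water = np.isin(reference.res_names, ["HOH", "WAT", "SOL", "TIP3", "SPC"])
    candidate &= ~water
    if not include_site_hydrogens:
        candidate &= heavy
    cand_idx = np.nonzero(candidate)[0]

    d = cdist(reference.coords[cand_idx], reference.coords[lig_heavy])
    site_idx = cand_idx[d.min(axis=1) <= cutoff]
    if len(site_idx) == 0:
        raise UsageError(
            f"no site atoms within {cutoff} A of the ligand; "
            "increase the cutoff"
        )
    ref_d = cdist(reference.coords[lig_heavy], reference.coords[site_idx])
    return BindingSiteDefinition(
        reference=reference,
        ligand_indices=lig_heavy,
        site_indices=site_idx,
        cutoff=float(cutoff),
        reference_distances=ref_d,
    )


def drmsd(model_coords: np.ndarray, site_def: BindingSiteDefinition,
          reference_coords: np.ndarray | None = None) -> float:
    """Distance-RMSD (A) between model and reference ligand-site distances.

    ``model_coords`` is a full-system coordinate set sharing the reference
    atom indexing.  Symmetric in the two structures; superposition-free.
    """
    model_coords = np.asarray(model_coords, dtype=np.float64)
    n_ref = site_def.reference.n_atoms
    if model_coords.shape != (n_ref, 3):
        raise StructureError(
            f"model coordinates have shape {model_coords.shape}; expected "
            f"({n_ref}, 3) matching the reference atom indexing"
        )
    if reference_coords is None:
        d_x = site_def.reference_distances
    else:
        reference_coords = np.asarray(reference_coords, dtype=np.float64)
        if reference_coords.shape != (n_ref, 3):
            raise StructureError("reference coordinate shape mismatch")
        d_x = cdist(reference_coords[site_def.ligand_indices],
                    reference_coords[site_def.site_indices])
    d_m = cdist(model_coords[site_def.ligand_indices],
                model_coords[site_def.site_indices])
    return float(np.sqrt(np.mean((d_x - d_m) ** 2)))


# ---------------------------------------------------------------------------
# cross-structure site RMSD
# ---------------------------------------------------------------------------

@dataclass
class SiteRMSDResult:
    rmsd: float
    n_matched: int
    n_dropped_a: int
    n_dropped_b: int

    def __float__(self) -> float:
        return self.rmsd


def _match_atoms(a: MolecularSystem, idx_a: np.ndarray,
                 b: MolecularSystem, idx_b: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Pair atoms by (chain, resid, inscode, name); order follows A."""
    keys_a = a.atom_keys()
    keys_b = b.atom_keys()
    map_b = {keys_b[i]: i for i in idx_b}
    out_a, out_b = [], []
    for i in idx_a:
        j = map_b.get(keys_a[i])
        if j is not None:
            out_a.append(i)
            out_b.append(j)
    return np.asarray(out_a, dtype=np.intp), np.asarray(out_b, dtype=np.intp)


def pairwise_site_rmsd(struct_a: MolecularSystem, struct_b: MolecularSystem,
                       site_expression: str, fit: bool = True
                       ) -> SiteRMSDResult:
    """Heavy-atom RMSD over a residue selection matched across two
    structures (by chain/residue number/atom name), after a Kabsch fit on
    the same atoms when ``fit`` is true.  Unmatched atoms are dropped and
    counted in the result.
    """
    sel_a = select(struct_a, site_expression)
    sel_b = select(struct_b, site_expression)
    ia, ib = _match_atoms(struct_a, sel_a.indices, struct_b, sel_b.indices)
    if len(ia) < 3:
        raise StructureError(
            f"only {len(ia)} matched site atoms; need >= 3 for superposition"
        )
    dropped_a = len(sel_a) - len(ia)
    dropped_b = len(sel_b) - len(ia)
    if dropped_a or dropped_b:
        warnings.warn(
            f"site match dropped {dropped_a} atoms from A and "
            f"{dropped_b} from B"
        )
    pa = struct_a.coords[ia]
    pb = struct_b.coords[ib]
    if fit:
        pb_fit, value = superpose(pb, pa)
        value = rmsd(pb_fit, pa)
    else:
        value = rmsd(pb, pa)
    return SiteRMSDResult(rmsd=value, n_matched=len(ia),
                         n_dropped_a=dropped_a, n_dropped_b=dropped_b)


# ---------------------------------------------------------------------------
# per-frame monitors
# ---------------------------------------------------------------------------

def _indices(sel: Selection | np.ndarray) -> np.ndarray:
    return np.asarray(getattr(sel, "indices", sel), dtype=np.intp)


def min_residue_distance(traj: Trajectory,
                         ligand_selection: Selection | np.ndarray,
                         residue_selection: Selection | np.ndarray
                         ) -> np.ndarray:
    """Per-frame minimum over all (ligand atom, residue atom) distances."""
    lig = _indices(ligand_selection)
    res = _indices(residue_selection)
    if len(lig) == 0 or len(res) == 0:
        raise UsageError("both selections must be nonempty")
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        out[f] = cdist(traj.coords[f, lig], traj.coords[f, res]).min()
    return out


def frames_below(series: np.ndarray, threshold: float) -> np.ndarray:
    """Frame indices where the series is strictly below the threshold."""
    return np.nonzero(np.asarray(series) < threshold)[0]


@dataclass
class SaltBridgeSeries:
    distances: np.ndarray      # min acidic-O to basic-N distance per frame
    broken: np.ndarray         # distance > broken_cutoff
    broken_cutoff: float

    @property
    def longest_broken_stretch(self) -> int:
        best = run = 0
        for flag in self.broken:
            run = run + 1 if flag else 0
            best = max(best, run)
        return best


def salt_bridge_series(traj: Trajectory,
                       acidic_selection: Selection | np.ndarray,
                       basic_selection: Selection | np.ndarray,
                       broken_cutoff: float = 4.5) -> SaltBridgeSeries:
    """Minimum distance between the acidic and basic atom groups per frame,
    flagged broken where it exceeds ``broken_cutoff`` (default 4.5 A, the
    common N-O salt-bridge criterion)."""
    d = min_residue_distance(traj, acidic_selection, basic_selection)
    return SaltBridgeSeries(distances=d, broken=d > broken_cutoff,
                            broken_cutoff=float(broken_cutoff))


def region_rmsd_series(traj: Trajectory,
                       region_selection: Selection | np.ndarray,
                       reference: MolecularSystem,
                       fit_selection: Selection | np.ndarray | None = None
                       ) -> np.ndarray:
    """Per-frame RMSD of a region after a global fit to the reference.

    Each frame is superposed on the reference over ``fit_selection``
    (default: protein CA atoms); the RMSD is then computed on the region
    atoms without refitting, so rigid displacements of the region relative
    to the fitted frame are reported at full magnitude.
    """
    region = _indices(region_selection)
    if len(region) == 0:
        raise UsageError("region selection is empty")
    if fit_selection is None:
        fit_selection = select(traj.system, "protein and name CA")
    fit_idx = _indices(fit_selection)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        moved, _ = superpose(traj.coords[f], reference.coords, fit_idx)
        out[f] = rmsd(moved[region], reference.coords[region])
    return out
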