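import numpy as np
import pytest

from ligmode.binding_site import (
    define_binding_site,
    drmsd,
    frames_below,
    min_residue_distance,
    pairwise_site_rmsd,
    region_rmsd_series,
    salt_bridge_series,
)
from ligmode.errors import StructureError, UsageError
from ligmode.trajio import select, superpose

from conftest import make_system, make_trajectory, random_rotation


def _ligand_system(protein_coords, ligand_coords):
    coords = np.vstack([ligand_coords, protein_coords])
    n_lig = len(ligand_coords)
    n = len(coords)
    return make_system(
        coords,
        names=[f"L{i}" for i in range(n_lig)]
        + [f"C{i}" for i in range(n - n_lig)],
        elements=["C"] * n,
        res_names=["LIG"] * n_lig + ["ALA"] * (n - n_lig),
        het=[True] * n_lig + [False] * (n - n_lig),
    )


class TestDefineBindingSite:
    def test_boundary_cutoff(self):
        system = _ligand_system([[5.0, 0, 0], [7.0, 0, 0]], [[0.0, 0, 0]])
        site = define_binding_site(system, select(system, "resname LIG"),
                                   cutoff=6.0)
        assert len(site.site_indices) == 1
        assert site.n_pairs == 1

    def test_zero_cutoff_errors(self):
        system = _ligand_system([[5.0, 0, 0]], [[0.0, 0, 0]])
        with pytest.raises(UsageError, match="cutoff"):
            define_binding_site(system, select(system, "resname LIG"),
                                cutoff=0.0)

    def test_matches_bruteforce_pair_filter(self, rng):
        lig = rng.uniform(0, 10, size=(5, 3))
        prot = rng.uniform(0, 20, size=(45, 3))
        system = _ligand_system(prot, lig)
        cutoff = 6.0
        site = define_binding_site(system, select(system, "resname LIG"),
                                   cutoff=cutoff)
        expected = [
            5 + i for i in range(45)
            if min(np.linalg.norm(prot[i] - lig_atom) for lig_atom in lig)
            <= cutoff
        ]
        assert site.site_indices.tolist() == expected
        assert site.n_pairs == 5 * len(expected)

    def test_empty_ligand_selection(self):
        system = _ligand_system([[1.0, 0, 0]], [[0.0, 0, 0]])
        with pytest.raises(UsageError):
            define_binding_site(system, np.array([], dtype=int))


def drmsd_oracle(model, reference, lig_idx, site_idx):
    """Independent double-loop evaluation of the distance-RMSD formula."""
    total = 0.0
    n = 0
    for i in lig_idx:
        for j in site_idx:
            dx = np.linalg.norm(reference[i] - reference[j])
            dm = np.linalg.norm(model[i] - model[j])
            total += (dx - dm) ** 2
            n += 1
    return np.sqrt(total / n)


class TestDrmsd:
    def test_identical_is_zero(self, rng):
        system = _ligand_system(rng.uniform(0, 8, (20, 3)),
                                rng.uniform(2, 6, (5, 3)))
        site = define_binding_site(system, select(system, "resname LIG"),
                                   cutoff=8.0)
        assert drmsd(system.coords, site) == 0.0

    def test_hand_computed_example(self):
        # 1 ligand atom; reference site distances (3, 4); model (4, 4)
        reference = _ligand_system([[3.0, 0, 0], [0, 4.0, 0]], [[0.0, 0, 0]])
        site = define_binding_site(reference,
                                   select(reference, "resname LIG"),
                                   cutoff=6.0)
        model = np.array([[0.0, 0, 0], [4.0, 0, 0], [0, 4.0, 0]])
        expected = np.sqrt((1.0 ** 2 + 0.0 ** 2) / 2)
        assert drmsd(model, site) == pytest.approx(expected, abs=1e-12)
        assert drmsd(model, site) == pytest.approx(0.7071, abs=1e-4)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        system = _ligand_system(rng.uniform(0, 8, (10, 3)),
                                rng.uniform(2, 6, (4, 3)))
        site = define_binding_site(system, select(system, "resname LIG"),
                                   cutoff=10.0)
        model = system.coords + rng.normal(scale=0.5, size=system.coords.shape)
        forward = drmsd(model, site)
        backward = drmsd(system.coords, site, reference_coords=model)
        assert forward == pytest.approx(backward, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        system = _ligand_system(rng.uniform(0, 12, (20, 3)),
                                rng.uniform(3, 9, (5, 3)))
        site = define_binding_site(system, select(system, "resname LIG"),
                                   cutoff=15.0)
        model = system.coords + rng.normal(scale=1.0, size=system.coords.shape)
        expected = drmsd_oracle(model, system.coords,
                                site.ligand_indices, site.site_indices)
        assert drmsd(model, site) == pytest.approx(expected, abs=1e-9)

    def test_rigid_invariance(self, rng):
        system = _ligand_system(rng.uniform(0, 8, (10, 3)),
                                rng.uniform(2, 6, (4, 3)))
        site = define_binding_site(system, select(system, "resname LIG"),
                                   cutoff=10.0)
        model = system.coords + rng.normal(scale=0.5, size=system.coords.shape)
        base = drmsd(model, site)
        R = random_rotation(rng)
        assert drmsd(model @ R.T + [3, 2, 1], site) == pytest.approx(
            base, abs=1e-9)

    def test_shape_mismatch_errors(self, rng):
        system = _ligand_system(rng.uniform(0, 8, (5, 3)),
                                rng.uniform(2, 6, (2, 3)))
        site = define_binding_site(system, select(system, "resname LIG"),
                                   cutoff=10.0)
        with pytest.raises(StructureError):
            drmsd(np.zeros((3, 3)), site)


class TestPairwiseSiteRMSD:
    def test_identical_structures(self, rng):
        system = make_system(rng.uniform(0, 10, (10, 3)),
                             names=["CA"] * 10, res_ids=range(1, 11))
        result = pairwise_site_rmsd(system, system, "name CA")
        assert result.rmsd == pytest.approx(0.0, abs=1e-9)
        assert result.n_matched == 10

    def test_fit_semantics(self, rng):
        coords = rng.uniform(0, 10, (8, 3))
        a = make_system(coords, names=["CA"] * 8, res_ids=range(1, 9))
        R = random_rotation(rng)
        b = a.with_coords(coords @ R.T + [5, 0, 0])
        fitted = pairwise_site_rmsd(a, b, "name CA", fit=True)
        unfitted = pairwise_site_rmsd(a, b, "name CA", fit=False)
        assert fitted.rmsd == pytest.approx(0.0, abs=1e-9)
        assert unfitted.rmsd > 1.0

    def test_symmetry(self, rng):
        coords = rng.uniform(0, 10, (8, 3))
        a = make_system(coords, names=["CA"] * 8, res_ids=range(1, 9))
        b = a.with_coords(coords + rng.normal(scale=0.8, size=coords.shape))
        ab = pairwise_site_rmsd(a, b, "name CA").rmsd
        ba = pairwise_site_rmsd(b, a, "name CA").rmsd
        assert ab == pytest.approx(ba, abs=1e-6)

    def test_unmatched_atoms_dropped_and_reported(self, rng):
        coords = rng.uniform(0, 10, (8, 3))
        a = make_system(coords, names=["CA"] * 8, res_ids=range(1, 9))
        # b lacks residues 7-8
        b = make_system(coords[:6], names=["CA"] * 6, res_ids=range(1, 7))
        with pytest.warns(UserWarning, match="dropped"):
            result = pairwise_site_rmsd(a, b, "name CA")
        assert result.n_matched == 6
        assert result.n_dropped_a == 2
        assert result.n_dropped_b == 0

    def test_too_few_matched(self, rng):
        a = make_system(rng.uniform(0, 5, (2, 3)), names=["CA", "CA"],
                        res_ids=[1, 2])
        with pytest.raises(StructureError):
            pairwise_site_rmsd(
                a, make_system(np.zeros((1, 3)), names=["CA"], res_ids=[9]),
                "name CA")


class TestMonitors:
    def test_constant_distance(self):
        system = _ligand_system([[3.0, 0, 0]], [[0.0, 0, 0]])
        traj = make_trajectory(system, np.repeat(system.coords[None], 4, 0))
        series = min_residue_distance(
            traj, select(system, "resname LIG"), np.array([1]))
        assert np.allclose(series, 3.0)

    def test_frame_filter_strict(self):
        series = np.array([6.0, 5.4, 5.5])
        assert frames_below(series, 5.5).tolist() == [1]

    def test_min_distance_bruteforce(self, rng):
        lig = rng.uniform(0, 10, (5, 3))
        prot = rng.uniform(0, 10, (25, 3))
        system = _ligand_system(prot, lig)
        frames = rng.uniform(0, 10, (6, 30, 3))
        traj = make_trajectory(system, frames)
        series = min_residue_distance(
            traj, select(system, "resname LIG"), np.arange(5, 30))
        for f in range(6):
            expected = min(
                np.linalg.norm(frames[f, i] - frames[f, j])
                for i in range(5) for j in range(5, 30)
            )
            assert series[f] == pytest.approx(expected, abs=1e-12)

    def test_salt_bridge_never_broken(self):
        system = make_system([[0, 0, 0], [3.0, 0, 0]],
                             names=["OE1", "NH1"], elements=["O", "N"])
        traj = make_trajectory(system, np.repeat(system.coords[None], 5, 0))
        result = salt_bridge_series(traj, np.array([0]), np.array([1]))
        assert not result.broken.any()
        assert result.longest_broken_stretch == 0

    def test_salt_bridge_broken_stretch(self):
        system = make_system([[0, 0, 0], [3.0, 0, 0]],
                             names=["OE1", "NH1"], elements=["O", "N"])
        frames = np.repeat(system.coords[None], 4, 0)
        frames[1, 1, 0] = 5.0
        frames[2, 1, 0] = 5.0
        traj = make_trajectory(system, frames)
        result = salt_bridge_series(traj, np.array([0]), np.array([1]),
                                    broken_cutoff=4.5)
        assert result.broken.tolist() == [False, True, True, False]
        assert result.longest_broken_stretch == 2

    def test_salt_bridge_bruteforce_min(self, rng):
        system = make_system(rng.uniform(0, 8, (10, 3)), elements=["O"] * 10)
        frames = rng.uniform(0, 8, (3, 10, 3))
        traj = make_trajectory(system, frames)
        acidic, basic = np.arange(4), np.arange(4, 10)
        result = salt_bridge_series(traj, acidic, basic)
        for f in range(3):
            expected = min(np.linalg.norm(frames[f, i] - frames[f, j])
                           for i in acidic for j in basic)
            assert result.distances[f] == pytest.approx(expected, abs=1e-12)


class TestRegionRMSD:
    def _system(self, rng):
        # 20 scaffold CA atoms + 5-atom region
        coords = np.vstack([rng.uniform(0, 20, (20, 3)),
                            rng.uniform(0, 20, (5, 3))])
        return make_system(coords, names=["CA"] * 25, elements=["C"] * 25)

    def test_repeated_reference_is_zero(self, rng):
        system = self._system(rng)
        traj = make_trajectory(system, np.repeat(system.coords[None], 4, 0))
        series = region_rmsd_series(traj, np.arange(20, 25), system,
                                    fit_selection=np.arange(20))
        assert np.allclose(series, 0.0, atol=1e-9)

    def test_displaced_region_reports_shift(self, rng):
        system = self._system(rng)
        frames = np.repeat(system.coords[None], 3, 0)
        frames[1:, 20:] += [5.0, 0, 0]   # rigid 5 A displacement
        traj = make_trajectory(system, frames)
        series = region_rmsd_series(traj, np.arange(20, 25), system,
                                    fit_selection=np.arange(20))
        assert series[0] == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(series[1:], 5.0, atol=1e-9)

    def test_refit_on_region_not_larger(self, rng):
        system = self._system(rng)
        frames = np.repeat(system.coords[None], 3, 0)
        frames[1] += rng.normal(scale=1.0, size=(25, 3))
        frames[2, 20:] += [4.0, 1.0, 0]
        traj = make_trajectory(system, frames)
        region = np.arange(20, 25)
        no_refit = region_rmsd_series(traj, region, system,
                                      fit_selection=np.arange(20))
        for f in range(3):
            _, refit = superpose(traj.coords[f, region],
                                 system.coords[region])
            assert refit <= no_refit[f] + 1e-9

    def test_empty_region_errors(self, rng):
        system = self._system(rng)
        traj = make_trajectory(system, system.coords[None])
        with pytest.raises(UsageError):
            region_rmsd_series(traj, np.array([], dtype=int), system,
                               fit_selection=np.arange(20))
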