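import numpy as np
import pytest

from ligmode.trajio import MolecularSystem, Trajectory


def make_system(coords, names=None, elements=None, res_names=None,
                res_ids=None, chain_ids=None, het=None):
    """Build an in-memory system with sensible defaults for tests."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    names = np.array(names if names is not None else [f"C{i}" for i in range(n)])
    if elements is None:
        elements = np.array([name.lstrip("0123456789")[0] for name in names])
    else:
        elements = np.array(elements)
    res_names = np.array(res_names if res_names is not None else ["ALA"] * n)
    res_ids = np.array(res_ids if res_ids is not None else np.arange(1, n + 1),
                       dtype=int)
    chain_ids = np.array(chain_ids if chain_ids is not None else ["A"] * n)
    het = np.array(het if het is not None else [False] * n, dtype=bool)
    return MolecularSystem(
        serials=np.arange(1, n + 1),
        names=names,
        elements=elements,
        res_names=res_names,
        res_ids=res_ids,
        chain_ids=chain_ids,
        ins_codes=np.array([""] * n),
        het_flags=het,
        coords=coords,
    )


def make_trajectory(system, frames, dt=0.1):
    frames = np.asarray(frames, dtype=float)
    return Trajectory(system=system, coords=frames,
                      times=dt * np.arange(len(frames)))


def random_rotation(rng):
    """Uniform random proper rotation matrix (QR with sign fix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_complex():
    from ligmode.synthetic_data import make_toy_complex

    return make_toy_complex(seed=1)
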