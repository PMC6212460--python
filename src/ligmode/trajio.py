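"""Structure/trajectory I/O, atom selection and rigid-body superposition.

Conventions used throughout the package:

* coordinates are in Angstrom, times in nanoseconds;
* frame indices are 0-based;
* residue numbers are kept exactly as in the source file (PDB 1-based
  numbering is never renumbered);
* no periodic-boundary imaging is performed -- inputs are assumed whole.

File parsing is delegated to `biotite` (PDB/GRO, multi-model PDB) and
`MDAnalysis` (XTC/DCD); this module owns the in-memory model, the
selection grammar and the Kabsch fit.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import (
    DegenerateFitError,
    ParseError,
    SelectionSyntaxError,
    StructureError,
    TrajectoryIOError,
    UsageError,
)

__all__ = [
    "MolecularSystem",
    "Trajectory",
    "Selection",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "select",
    "superpose",
    "kabsch",
    "rmsd",
    "check_continuity",
]

_WATER_RESNAMES = frozenset({"HOH", "WAT", "SOL", "TIP3", "TIP4", "SPC"})


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MolecularSystem:
    """Ordered atom records plus a single coordinate set (Angstrom).

    Atom order is stable across every operation in the package; residues
    are keyed by (chain, residue number, insertion code).
    """

    serials: np.ndarray        # int, original atom ids
    names: np.ndarray          # str, atom names
    elements: np.ndarray       # str, element symbols ('' if unknown)
    res_names: np.ndarray      # str
    res_ids: np.ndarray        # int, as in the source file
    chain_ids: np.ndarray      # str
    ins_codes: np.ndarray      # str, '' when absent
    het_flags: np.ndarray      # bool, HETATM records
    coords: np.ndarray         # (n_atoms, 3) float64, Angstrom

    def __post_init__(self) -> None:
        n = len(self.names)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.shape != (n, 3):
            raise StructureError(
                f"coordinate array has shape {self.coords.shape}, expected ({n}, 3)"
            )
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates in structure")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def heavy_mask(self) -> np.ndarray:
        """True for non-hydrogen atoms.

        Uses the element field when present; otherwise the first
        alphabetic character of the atom name after leading digits.
        """
        mask = np.empty(self.n_atoms, dtype=bool)
        for i in range(self.n_atoms):
            elem = self.elements[i].strip()
            if elem:
                mask[i] = elem.upper() not in ("H", "D")
            else:
                stripped = self.names[i].lstrip("0123456789 ")
                mask[i] = not (stripped[:1].upper() in ("H", "D"))
        return mask

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Per-atom (chain, res_id, insertion code) keys."""
        return [
            (self.chain_ids[i], int(self.res_ids[i]), self.ins_codes[i])
            for i in range(self.n_atoms)
        ]

    def atom_keys(self) -> list[tuple[str, int, str, str]]:
        """Per-atom (chain, res_id, ins_code, atom name) correspondence keys."""
        return [
            (self.chain_ids[i], int(self.res_ids[i]), self.ins_codes[i], self.names[i])
            for i in range(self.n_atoms)
        ]

    def subset(self, indices: np.ndarray) -> "MolecularSystem":
        """A new system containing only the given atoms, order preserved."""
        idx = np.asarray(indices, dtype=np.intp)
        return MolecularSystem(
            serials=self.serials[idx],
            names=self.names[idx],
            elements=self.elements[idx],
            res_names=self.res_names[idx],
            res_ids=self.res_ids[idx],
            chain_ids=self.chain_ids[idx],
            ins_codes=self.ins_codes[idx],
            het_flags=self.het_flags[idx],
            coords=self.coords[idx],
        )

    def with_coords(self, coords: np.ndarray) -> "MolecularSystem":
        """A copy of this system carrying a different coordinate set."""
        return MolecularSystem(
            serials=self.serials.copy(),
            names=self.names.copy(),
            elements=self.elements.copy(),
            res_names=self.res_names.copy(),
            res_ids=self.res_ids.copy(),
            chain_ids=self.chain_ids.copy(),
            ins_codes=self.ins_codes.copy(),
            het_flags=self.het_flags.copy(),
            coords=np.array(coords, dtype=np.float64),
        )


@dataclass
class Trajectory:
    """A topology plus ordered per-frame coordinate sets and times (ns)."""

    system: MolecularSystem
    coords: np.ndarray     # (n_frames, n_atoms, 3) float64, Angstrom
    times: np.ndarray      # (n_frames,) float64, ns, strictly increasing

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[1] != self.system.n_atoms:
            raise StructureError(
                f"trajectory frame atom count {self.coords.shape} does not "
                f"match topology ({self.system.n_atoms} atoms)"
            )
        if len(self.times) != self.coords.shape[0]:
            raise StructureError("times length does not match frame count")
        if len(self.times) > 0 and self.times[0] < 0:
            raise StructureError("times[0] must be >= 0")
        if len(self.times) > 1:
            gaps = np.diff(self.times)
            if np.any(gaps <= 0):
                raise StructureError("frame times must be strictly increasing")
            if np.max(np.abs(gaps - gaps[0])) > 1e-9:
                raise StructureError("frame interval dt is not uniform")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def dt(self) -> float:
        """Frame interval in ns, inferred from the first two times."""
        if self.n_frames < 2:
            raise UsageError("dt undefined for trajectories with < 2 frames")
        return float(self.times[1] - self.times[0])

    def frame(self, i: int) -> MolecularSystem:
        return self.system.with_coords(self.coords[i])


@dataclass
class Selection:
    """Sorted unique atom indices plus the expression that produced them."""

    indices: np.ndarray
    expression: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.intp)
        if len(self.indices) > 1:
            if np.any(np.diff(self.indices) <= 0):
                raise UsageError("selection indices must be unique and ascending")

    def __len__(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# structure I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _from_atom_array(arr) -> MolecularSystem:
    import biotite.structure as struc  # noqa: F401

    n = arr.array_length()
    serials = (
        arr.get_annotation("atom_id")
        if "atom_id" in arr.get_annotation_categories()
        else np.arange(1, n + 1)
    )
    ins = (
        arr.get_annotation("ins_code")
        if "ins_code" in arr.get_annotation_categories()
        else np.array([""] * n)
    )
    chains = np.array([c if c.strip() else "A" for c in arr.chain_id])
    return MolecularSystem(
        serials=np.asarray(serials, dtype=int),
        names=np.array(arr.atom_name),
        elements=np.array(arr.element),
        res_names=np.array(arr.res_name),
        res_ids=np.asarray(arr.res_id, dtype=int),
        chain_ids=chains,
        ins_codes=np.array([i.strip() for i in ins]),
        het_flags=np.asarray(arr.hetero, dtype=bool),
        coords=np.asarray(arr.coord, dtype=np.float64),
    )


def _to_atom_array(system: MolecularSystem, coords: np.ndarray | None = None):
    import biotite.structure as struc

    arr = struc.AtomArray(system.n_atoms)
    arr.coord = np.asarray(
        coords if coords is not None else system.coords, dtype=np.float32
    )
    arr.chain_id = system.chain_ids.astype("U4")
    arr.res_id = system.res_ids.astype(int)
    arr.res_name = system.res_names.astype("U5")
    arr.atom_name = system.names.astype("U6")
    arr.element = system.elements.astype("U2")
    arr.hetero = system.het_flags.astype(bool)
    arr.set_annotation("atom_id", system.serials.astype(int))
    arr.set_annotation("ins_code", system.ins_codes.astype("U1"))
    return arr


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = Path(path).suffix.lower().lstrip(".")
    return suffix


def read_structure(path: str | Path, format: str | None = None) -> MolecularSystem:
    """Read a single-frame structure from a PDB or GRO file.

    PDB alternate locations are resolved to the highest-occupancy
    conformer (ties go to the first listed, conventionally 'A').
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"structure file not found: {path}")
    fmt = _infer_format(path, format)
    try:
        if fmt == "pdb":
            from biotite.structure.io.pdb import PDBFile

            pdb = PDBFile.read(str(path))
            arr = pdb.get_structure(
                model=1, altloc="occupancy", extra_fields=["atom_id"]
            )
        elif fmt == "gro":
            from biotite.structure.io.gro import GROFile

            gro = GROFile.read(str(path))
            arr = gro.get_structure(model=1)
        else:
            raise UsageError(f"unknown structure format: {fmt!r} (use pdb or gro)")
    except UsageError:
        raise
    except Exception as exc:  # biotite raises assorted parse exceptions
        raise ParseError(f"cannot parse {path} as {fmt}: {exc}") from exc
    return _from_atom_array(arr)


def write_structure(system: MolecularSystem, path: str | Path,
                    format: str | None = None) -> None:
    """Write a structure to PDB or GRO; readable by mainstream viewers."""
    path = Path(path)
    fmt = _infer_format(path, format)
    arr = _to_atom_array(system)
    if fmt == "pdb":
        from biotite.structure.io.pdb import PDBFile

        out = PDBFile()
        out.set_structure(arr)
        out.write(str(path))
    elif fmt == "gro":
        from biotite.structure.io.gro import GROFile

        out = GROFile()
        out.set_structure(arr)
        out.write(str(path))
    else:
        raise UsageError(f"unknown structure format: {fmt!r} (use pdb or gro)")


# ---------------------------------------------------------------------------
# trajectory I/O
# ---------------------------------------------------------------------------

def _uniform_times(raw_times_ns: np.ndarray, n_frames: int) -> np.ndarray:
    """Snap near-uniform times from binary formats to an exact grid."""
    if n_frames < 2:
        return np.asarray(raw_times_ns, dtype=np.float64)
    raw = np.asarray(raw_times_ns, dtype=np.float64)
    dt = raw[1] - raw[0]
    if dt <= 0:
        raise TrajectoryIOError("non-increasing frame times in trajectory")
    gaps = np.diff(raw)
    if np.max(np.abs(gaps - dt)) > max(1e-4, 1e-3 * dt):
        # genuinely non-uniform; keep as read
        return raw
    return raw[0] + dt * np.arange(n_frames)


def read_trajectory(topology_path: str | Path, traj_path: str | Path,
                    format: str | None = None, dt: float | None = None,
                    stride: int = 1) -> Trajectory:
    """Read a trajectory (XTC, DCD or multi-model PDB) onto a topology.

    ``dt`` (ns) is only used for multi-model PDB, which stores no times;
    XTC/DCD times are taken from the file (ps converted to ns).
    """
    system = read_structure(topology_path)
    traj_path = Path(traj_path)
    if not traj_path.exists():
        raise TrajectoryIOError(f"trajectory file not found: {traj_path}")
    fmt = _infer_format(traj_path, format)
    if fmt in ("multipdb", "pdb"):
        coords, times = _read_multipdb(traj_path, dt=dt)
    elif fmt in ("xtc", "dcd"):
        coords, times = _read_mda(traj_path, fmt)
    else:
        raise UsageError(f"unknown trajectory format: {fmt!r}")
    if coords.shape[1] != system.n_atoms:
        raise StructureError(
            f"trajectory has {coords.shape[1]} atoms but topology "
            f"{topology_path} has {system.n_atoms}"
        )
    if stride < 1:
        raise UsageError("stride must be >= 1")
    if stride > 1:
        coords = coords[::stride]
        times = times[::stride]
    return Trajectory(system=system, coords=coords,
                      times=_uniform_times(times, len(times)))


def _read_multipdb(path: Path, dt: float | None) -> tuple[np.ndarray, np.ndarray]:
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        obj = pdb.get_structure(altloc="occupancy")
    except Exception as exc:
        raise ParseError(f"cannot parse multi-model PDB {path}: {exc}") from exc
    coord = np.asarray(obj.coord, dtype=np.float64)
    if coord.ndim == 2:
        coord = coord[None]
    n_frames = coord.shape[0]
    step = 1.0 if dt is None else float(dt)
    return coord, step * np.arange(n_frames)


def _read_mda(path: Path, fmt: str) -> tuple[np.ndarray, np.ndarray]:
    import MDAnalysis as mda

    try:
        reader_cls = (mda.coordinates.XTC.XTCReader if fmt == "xtc"
                      else mda.coordinates.DCD.DCDReader)
        reader = reader_cls(str(path))
    except Exception as exc:
        raise TrajectoryIOError(f"cannot open {path}: {exc}") from exc
    frames = []
    times_ps = []
    idx = 0
    try:
        for ts in reader:
            frames.append(np.array(ts.positions, dtype=np.float64))
            times_ps.append(float(ts.time))
            idx += 1
    except Exception as exc:
        raise TrajectoryIOError(
            f"truncated or unreadable trajectory {path} at frame {idx}: {exc}"
        ) from exc
    finally:
        reader.close()
    return np.array(frames), np.array(times_ps) / 1000.0


def write_trajectory(traj: Trajectory, path: str | Path,
                     format: str | None = None) -> None:
    """Write a trajectory as XTC, DCD or multi-model PDB."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt in ("multipdb", "pdb"):
        import biotite.structure as struc
        from biotite.structure.io.pdb import PDBFile

        arrays = [_to_atom_array(traj.system, traj.coords[i])
                  for i in range(traj.n_frames)]
        stack = struc.stack(arrays)
        out = PDBFile()
        out.set_structure(stack)
        out.write(str(path))
    elif fmt == "xtc":
        import MDAnalysis as mda
        from MDAnalysis.coordinates.XTC import XTCWriter

        u = mda.Universe.empty(traj.system.n_atoms, trajectory=True)
        with XTCWriter(str(path), n_atoms=traj.system.n_atoms) as writer:
            for i in range(traj.n_frames):
                u.atoms.positions = traj.coords[i].astype(np.float32)
                u.trajectory.ts.time = traj.times[i] * 1000.0  # ns -> ps
                u.trajectory.ts.frame = i
                writer.write(u.atoms)
    elif fmt == "dcd":
        import MDAnalysis as mda
        from MDAnalysis.coordinates.DCD import DCDWriter

        u = mda.Universe.empty(traj.system.n_atoms, trajectory=True)
        dt_ps = (traj.dt * 1000.0) if traj.n_frames > 1 else 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with DCDWriter(str(path), n_atoms=traj.system.n_atoms,
                           dt=dt_ps) as writer:
                for i in range(traj.n_frames):
                    u.atoms.positions = traj.coords[i].astype(np.float32)
                    writer.write(u.atoms)
    else:
        raise UsageError(f"unknown trajectory format: {fmt!r}")


def check_continuity(traj: Trajectory, max_jump: float = 20.0) -> list[tuple[int, int]]:
    """Flag (frame, atom) pairs whose inter-frame displacement exceeds
    ``max_jump`` Angstrom -- a sign of unimaged periodic coordinates."""
    offenders: list[tuple[int, int]] = []
    for i in range(1, traj.n_frames):
        disp = np.linalg.norm(traj.coords[i] - traj.coords[i - 1], axis=1)
        for atom in np.nonzero(disp > max_jump)[0]:
            offenders.append((i, int(atom)))
    if offenders:
        warnings.warn(
            f"{len(offenders)} inter-frame atom jumps exceed {max_jump} A; "
            "input may not be whole/imaged"
        )
    return offenders


# ---------------------------------------------------------------------------
# selection grammar
# ---------------------------------------------------------------------------
#
#   expr     := or_expr
#   or_expr  := and_expr ('or' and_expr)*
#   and_expr := unary ('and' unary)*
#   unary    := 'not' unary | primary
#   primary  := '(' expr ')'
#             | 'within' NUMBER 'of' primary
#             | 'resname' WORD+ | 'resid' (INT | INT:INT)+ | 'name' WORD+
#             | 'chain' WORD+ | 'element' WORD+
#             | 'heavy' | 'hydrogen' | 'water' | 'protein' | 'all' | 'none'
#
# `within R of S` selects every atom whose minimum Euclidean distance to
# any atom of S is <= R (inclusive), evaluated on the system's coordinate
# set; the atoms of S themselves are therefore included (distance 0).

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")

_KEYWORDS = {
    "and", "or", "not", "within", "of", "resname", "resid", "name",
    "chain", "element", "heavy", "hydrogen", "water", "protein",
    "all", "none", "(", ")",
}


class _Parser:
    def __init__(self, expression: str, system: MolecularSystem):
        self.expression = expression
        self.system = system
        self.tokens: list[tuple[str, int]] = [
            (m.group(0), m.start()) for m in _TOKEN_RE.finditer(expression)
        ]
        self.pos = 0

    # -- token helpers -----------------------------------------------------
    def _peek(self) -> str | None:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def _next(self) -> tuple[str, int]:
        if self.pos >= len(self.tokens):
            raise SelectionSyntaxError(
                "unexpected end of expression", len(self.expression)
            )
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    # -- grammar -----------------------------------------------------------
    def parse(self) -> np.ndarray:
        mask = self._or_expr()
        if self.pos != len(self.tokens):
            tok, at = self.tokens[self.pos]
            raise SelectionSyntaxError(f"unexpected token {tok!r}", at)
        return mask

    def _or_expr(self) -> np.ndarray:
        mask = self._and_expr()
        while self._peek() == "or":
            self._next()
            mask = mask | self._and_expr()
        return mask

    def _and_expr(self) -> np.ndarray:
        mask = self._unary()
        while self._peek() == "and":
            self._next()
            mask = mask & self._unary()
        return mask

    def _unary(self) -> np.ndarray:
        if self._peek() == "not":
            self._next()
            return ~self._unary()
        return self._primary()

    def _primary(self) -> np.ndarray:
        tok, at = self._next()
        sys = self.system
        if tok == "(":
            mask = self._or_expr()
            closing, cat = self._next()
            if closing != ")":
                raise SelectionSyntaxError("expected ')'", cat)
            return mask
        if tok == "within":
            rtok, rat = self._next()
            try:
                radius = float(rtok)
            except ValueError:
                raise SelectionSyntaxError(
                    f"expected a distance after 'within', got {rtok!r}", rat
                ) from None
            of_tok, of_at = self._next()
            if of_tok != "of":
                raise SelectionSyntaxError("expected 'of' after 'within R'", of_at)
            inner = self._unary()
            return _within_mask(sys.coords, inner, radius)
        if tok == "resname":
            return self._membership(lambda vals: np.isin(sys.res_names, vals), at)
        if tok == "name":
            return self._membership(lambda vals: np.isin(sys.names, vals), at)
        if tok == "chain":
            return self._membership(lambda vals: np.isin(sys.chain_ids, vals), at)
        if tok == "element":
            return self._membership(
                lambda vals: np.isin(
                    np.char.upper(sys.elements.astype(str)),
                    [v.upper() for v in vals],
                ),
                at,
            )
        if tok == "resid":
            ids = self._resid_values(at)
            return np.isin(sys.res_ids, ids)
        if tok == "heavy":
            return sys.heavy_mask()
        if tok == "hydrogen":
            return ~sys.heavy_mask()
        if tok == "water":
            return np.isin(sys.res_names, list(_WATER_RESNAMES))
        if tok == "protein":
            return (~sys.het_flags) & ~np.isin(sys.res_names, list(_WATER_RESNAMES))
        if tok == "all":
            return np.ones(sys.n_atoms, dtype=bool)
        if tok == "none":
            return np.zeros(sys.n_atoms, dtype=bool)
        raise SelectionSyntaxError(f"unexpected token {tok!r}", at)

    def _values(self, at: int) -> list[str]:
        vals: list[str] = []
        while (tok := self._peek()) is not None and tok not in _KEYWORDS:
            vals.append(self._next()[0])
        if not vals:
            raise SelectionSyntaxError("keyword requires at least one value", at)
        return vals

    def _membership(self, fn, at: int) -> np.ndarray:
        return fn(self._values(at))

    def _resid_values(self, at: int) -> np.ndarray:
        out: list[int] = []
        for raw in self._values(at):
            m = re.fullmatch(r"(-?\d+)[:-](-?\d+)", raw)
            if m:
                lo, hi = int(m.group(1)), int(m.group(2))
                out.extend(range(lo, hi + 1))
                continue
            try:
                out.append(int(raw))
            except ValueError:
                raise SelectionSyntaxError(
                    f"invalid residue id {raw!r}", at
                ) from None
        return np.asarray(out, dtype=int)


def _within_mask(coords: np.ndarray, inner_mask: np.ndarray,
                 radius: float) -> np.ndarray:
    """Atoms whose min distance to any atom of inner_mask is <= radius."""
    ref = coords[inner_mask]
    if len(ref) == 0:
        return np.zeros(len(coords), dtype=bool)
    from scipy.spatial import cKDTree

    tree = cKDTree(ref)
    dmin, _ = tree.query(coords, k=1)
    return dmin <= radius


def select(system: MolecularSystem, expression: str) -> Selection:
    """Evaluate a selection expression, returning sorted unique indices.

    Empty results are legal (a warning is emitted, not an error).
    """
    if not expression.strip():
        raise SelectionSyntaxError("empty selection expression", 0)
    mask = _Parser(expression, system).parse()
    indices = np.nonzero(mask)[0]
    if len(indices) == 0:
        warnings.warn(f"selection {expression!r} matched no atoms")
    return Selection(indices=indices, expression=expression)


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t mapping mobile onto
    reference in the least-squares sense (x' = x @ R.T + t); no reflection."""
    P = np.asarray(mobile, dtype=np.float64)
    Q = np.asarray(reference, dtype=np.float64)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - pc @ R.T
    return R, t


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD (no fitting) between matched atom sets."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise StructureError(f"coordinate shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superpose(mobile_coords: np.ndarray, reference_coords: np.ndarray,
              fit_indices: np.ndarray | None = None
              ) -> tuple[np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch, no reflection).

    The transform is determined on ``fit_indices`` (all atoms when None)
    and applied to *all* atoms of the mobile set.  Returns the transformed
    coordinates and the RMSD over the fit atoms.
    """
    mobile = np.asarray(mobile_coords, dtype=np.float64)
    reference = np.asarray(reference_coords, dtype=np.float64)
    if fit_indices is None:
        fit_indices = np.arange(len(mobile))
    fit_indices = np.asarray(fit_indices, dtype=np.intp)
    if len(fit_indices) < 3:
        raise DegenerateFitError(
            f"superposition requires >= 3 fit atoms, got {len(fit_indices)}"
        )
    P = mobile[fit_indices]
    Q = reference[fit_indices]
    if P.shape != Q.shape:
        raise StructureError(
            f"fit atom correspondence mismatch: {P.shape} vs {Q.shape}"
        )
    # collinearity: second singular value of the centered fit set ~ 0
    sv = np.linalg.svd(P - P.mean(axis=0), compute_uv=False)
    if len(P) >= 3 and sv[1] < 1e-8 * max(sv[0], 1.0):
        warnings.warn("fit atoms are (near-)collinear; rotation is ill-determined")
    R, t = kabsch(P, Q)
    transformed = mobile @ R.T + t
    return transformed, rmsd(transformed[fit_indices], Q)
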