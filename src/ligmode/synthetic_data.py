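"""Seedable toy complexes and trajectories for exercising the analyses.

The generators produce, without any MD engine:

* a spherical-shell "protein" enclosing a cavity, pierced by two labelled
  channel cones (A and B) with gate residues at their rims;
* ligand trajectories whose orientation is drawn from a mixture of
  von Mises-Fisher components, with optional scheduled escape events;
* tracer-water trajectories realizing a scripted list of entry/exit
  events through the named channels, with optional boundary flicker.

Every generator is bit-deterministic given (spec, seed), and each returns
a ground-truth record sufficient to score the downstream analyses.

Directional sampling uses the standard inversion method for the
von Mises-Fisher distribution on S2 (Ulrich 1984; Wood 1994): with mean
direction mu and concentration kappa, draw u ~ U(0,1) and set

    w = 1 + log(u + (1 - u) * exp(-2*kappa)) / kappa        (kappa > 0)
    w ~ U(-1, 1)                                            (kappa = 0)

then take a uniform angle alpha in [0, 2*pi) and the sample
(sqrt(1-w^2)*cos(alpha), sqrt(1-w^2)*sin(alpha), w) rotated so that
+z maps onto mu.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ScheduleError, SpecError
from .trajio import MolecularSystem, Trajectory

__all__ = [
    "ToyComplexSpec",
    "OrientationMixtureSpec",
    "ScheduledExchange",
    "BindingGroundTruth",
    "make_toy_complex",
    "simulate_binding_trajectory",
    "simulate_water_trajectory",
    "sample_vmf",
    "angles_to_unit",
    "unit_to_angles",
    "LIGAND_TEMPLATE",
    "LIGAND_ATOM_NAMES",
]

# Rigid 5-atom ligand template (Angstrom, local frame):
# hydroxyl oxygen at the origin, bridging carbon on +z, two phosphorus
# flanking it, and a ring-center dummy off-axis.
LIGAND_ATOM_NAMES = ("O1", "C1", "P1", "P2", "X1")
LIGAND_ELEMENTS = ("O", "C", "P", "P", "C")
LIGAND_TEMPLATE = np.array(
    [
        [0.0, 0.0, 0.0],   # O1  hydroxyl oxygen (rotation center)
        [0.0, 0.0, 2.5],   # C1  bridging carbon -> O1->C1 is the CV vector
        [1.5, 0.0, 3.6],   # P1
        [-1.5, 0.0, 3.6],  # P2
        [0.0, 1.4, 1.2],   # X1  ring-center dummy
    ],
    dtype=np.float64,
)


def angles_to_unit(theta_deg: float, phi_deg: float) -> np.ndarray:
    """Unit vector from polar angles (theta from +z, phi in the xy plane)."""
    th = math.radians(theta_deg)
    ph = math.radians(phi_deg)
    return np.array(
        [math.sin(th) * math.cos(ph), math.sin(th) * math.sin(ph), math.cos(th)]
    )


def unit_to_angles(u: np.ndarray) -> tuple[float, float]:
    """(theta, phi) in degrees; phi = 0 at the poles by convention."""
    u = np.asarray(u, dtype=np.float64)
    theta = math.degrees(math.acos(max(-1.0, min(1.0, u[2]))))
    if abs(u[0]) < 1e-12 and abs(u[1]) < 1e-12:
        return theta, 0.0
    phi = math.degrees(math.atan2(u[1], u[0]))
    if phi <= -180.0:
        phi = 180.0
    return theta, phi


def _rotation_z_to(u: np.ndarray) -> np.ndarray:
    """Minimal proper rotation taking +z onto the unit vector u."""
    u = np.asarray(u, dtype=np.float64)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, u))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # 180 deg about x
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(z, u)
    s = np.linalg.norm(axis)
    axis = axis / s
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    # Rodrigues with unit axis: R = I + sin(t) K + (1 - cos(t)) K^2
    return np.eye(3) + K * s + K @ K * (1.0 - c)


def sample_vmf(mean_direction: np.ndarray, kappa: float, n: int,
               rng: np.random.Generator) -> np.ndarray:
    """Draw n unit vectors from a von Mises-Fisher distribution on S2.

    kappa = 0 gives the uniform distribution on the sphere.
    """
    if kappa < 0:
        raise SpecError(f"vMF concentration must be >= 0, got {kappa}")
    mu = np.asarray(mean_direction, dtype=np.float64)
    norm = np.linalg.norm(mu)
    if norm < 1e-12:
        raise SpecError("vMF mean direction must be a nonzero vector")
    mu = mu / norm
    u = rng.random(n)
    if kappa == 0.0:
        w = 2.0 * u - 1.0
    else:
        w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
        w = np.clip(w, -1.0, 1.0)
    alpha = rng.random(n) * 2.0 * np.pi
    s = np.sqrt(np.clip(1.0 - w * w, 0.0, None))
    samples = np.stack([s * np.cos(alpha), s * np.sin(alpha), w], axis=1)
    return samples @ _rotation_z_to(mu).T


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class ToyComplexSpec:
    """Geometry of the toy cavity complex.

    The scaffold is a quasi-uniform spherical shell of pseudo-residues
    with two cone-shaped openings (channels A and B); gate residues sit
    on each cone rim.  r_in/r_out are the hysteresis radii the water
    analysis uses for this geometry.
    """

    n_scaffold_atoms: int = 200
    cavity_radius: float = 9.0
    channel_axis_a: tuple[float, float, float] = (1.0, 0.0, 0.0)
    channel_axis_b: tuple[float, float, float] = (
        math.cos(math.radians(150.0)), math.sin(math.radians(150.0)), 0.0)
    half_angle_a: float = 25.0
    half_angle_b: float = 25.0
    gate_resname_a: str = "GTA"
    gate_resname_b: str = "GTB"
    n_gate_atoms: int = 3
    r_in: float = 6.0
    r_out: float = 8.0

    def axis(self, channel: str) -> np.ndarray:
        raw = self.channel_axis_a if channel == "A" else self.channel_axis_b
        v = np.asarray(raw, dtype=np.float64)
        return v / np.linalg.norm(v)

    def half_angle(self, channel: str) -> float:
        return self.half_angle_a if channel == "A" else self.half_angle_b

    def validate(self) -> None:
        if self.n_scaffold_atoms < 10:
            raise SpecError("need at least 10 scaffold atoms")
        if self.cavity_radius <= self.r_out:
            raise SpecError("cavity radius must exceed r_out")
        if self.r_out - self.r_in < 0.5:
            raise SpecError("r_out - r_in must be >= 0.5 A")
        a, b = self.axis("A"), self.axis("B")
        angle = math.degrees(math.acos(max(-1.0, min(1.0, float(np.dot(a, b))))))
        if angle <= 20.0:
            raise SpecError(
                f"channel axes must be > 20 deg apart, got {angle:.1f} deg"
            )
        if self._cone_overlap_fraction() > 0.5:
            raise SpecError("channel cones overlap by more than 50%")

    def _cone_overlap_fraction(self) -> float:
        """Fraction of the smaller spherical cap shared with the other,
        estimated on a deterministic Fibonacci grid."""
        pts = _fibonacci_sphere(20000)
        in_a = _in_cone(pts, self.axis("A"), self.half_angle_a)
        in_b = _in_cone(pts, self.axis("B"), self.half_angle_b)
        smaller = min(in_a.sum(), in_b.sum())
        if smaller == 0:
            return 0.0
        return float((in_a & in_b).sum() / smaller)


@dataclass
class OrientationMixtureSpec:
    """Mixture of von Mises-Fisher components on the sphere.

    components: (mean_theta_deg, mean_phi_deg, kappa, weight); the
    weights must sum to 1.
    """

    components: list[tuple[float, float, float, float]] = field(
        default_factory=lambda: [(60.0, 150.0, 50.0, 1.0)]
    )

    def validate(self) -> None:
        if not self.components:
            raise SpecError("mixture needs at least one component")
        weights = [c[3] for c in self.components]
        if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
            raise SpecError("mixture weights must be nonnegative and sum to 1")
        for theta, phi, kappa, _w in self.components:
            if kappa < 0:
                raise SpecError(f"kappa must be >= 0, got {kappa}")
            if not (0.0 <= theta <= 180.0):
                raise SpecError(f"theta must be in [0, 180], got {theta}")


@dataclass(frozen=True)
class ScheduledExchange:
    """One scripted water crossing: ground truth for the detector."""

    water_id: int
    frame: int
    direction: str   # "entry" | "exit"
    channel: str     # "A" | "B"


@dataclass
class BindingGroundTruth:
    """Per-frame generator state for a binding trajectory."""

    component_ids: np.ndarray   # (n_frames,)
    thetas: np.ndarray          # (n_frames,) deg, drawn O->C direction
    phis: np.ndarray            # (n_frames,) deg
    escape_frame: int | None
    escape_channel: str | None


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (deterministic golden-angle spiral)."""
    i = np.arange(n, dtype=np.float64)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    golden = math.pi * (3.0 - math.sqrt(5.0))
    phi = golden * i
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _in_cone(unit_pts: np.ndarray, axis: np.ndarray, half_angle_deg: float
             ) -> np.ndarray:
    if half_angle_deg <= 0.0:
        return np.zeros(len(unit_pts), dtype=bool)
    return unit_pts @ axis >= math.cos(math.radians(half_angle_deg))


def make_toy_complex(spec: ToyComplexSpec | None = None, seed: int = 0
                     ) -> MolecularSystem:
    """Build the toy cavity complex: shell + gate residues + rigid ligand.

    Shell atoms lie on a sphere of ``cavity_radius`` except inside the two
    channel cones; gate residues (resname GTA/GTB by default) mark each
    cone rim; the ligand (resname LIG) sits at the cavity center with its
    hydroxyl oxygen at the origin.
    """
    spec = spec or ToyComplexSpec()
    spec.validate()
    rng = np.random.default_rng(seed)

    pts = _fibonacci_sphere(spec.n_scaffold_atoms)
    keep = ~(_in_cone(pts, spec.axis("A"), spec.half_angle_a)
             | _in_cone(pts, spec.axis("B"), spec.half_angle_b))
    shell = pts[keep] * spec.cavity_radius
    shell = shell + rng.normal(scale=0.05, size=shell.shape)  # seeded jitter

    names: list[str] = []
    elements: list[str] = []
    res_names: list[str] = []
    res_ids: list[int] = []
    chain_ids: list[str] = []
    het: list[bool] = []
    coords: list[np.ndarray] = []

    res_id = 0
    for xyz in shell:
        res_id += 1
        names.append("CA")
        elements.append("C")
        res_names.append("CAV")
        res_ids.append(res_id)
        chain_ids.append("A")
        het.append(False)
        coords.append(xyz)

    # gate residues on each cone rim, slightly outside the half-angle
    for channel, resname in (("A", spec.gate_resname_a),
                             ("B", spec.gate_resname_b)):
        axis = spec.axis(channel)
        rim_angle = math.radians(spec.half_angle(channel) + 2.0)
        Rz = _rotation_z_to(axis)
        for k in range(spec.n_gate_atoms):
            res_id += 1
            ang = 2.0 * math.pi * k / spec.n_gate_atoms
            local = np.array(
                [
                    math.sin(rim_angle) * math.cos(ang),
                    math.sin(rim_angle) * math.sin(ang),
                    math.cos(rim_angle),
                ]
            )
            names.append("CA")
            elements.append("N")
            res_names.append(resname)
            res_ids.append(res_id)
            chain_ids.append("A")
            het.append(False)
            coords.append(Rz @ local * spec.cavity_radius)

    lig_res_id = res_id + 1
    for name, element, xyz in zip(LIGAND_ATOM_NAMES, LIGAND_ELEMENTS,
                                  LIGAND_TEMPLATE):
        names.append(name)
        elements.append(element)
        res_names.append("LIG")
        res_ids.append(lig_res_id)
        chain_ids.append("L")
        het.append(True)
        coords.append(xyz)

    n = len(names)
    return MolecularSystem(
        serials=np.arange(1, n + 1),
        names=np.array(names),
        elements=np.array(elements),
        res_names=np.array(res_names),
        res_ids=np.array(res_ids, dtype=int),
        chain_ids=np.array(chain_ids),
        ins_codes=np.array([""] * n),
        het_flags=np.array(het, dtype=bool),
        coords=np.array(coords),
    )


def simulate_binding_trajectory(
    system: MolecularSystem,
    mixture: OrientationMixtureSpec,
    n_frames: int,
    dt: float,
    escape_frame: int | None = None,
    seed: int = 0,
    spec: ToyComplexSpec | None = None,
    escape_channel: str = "B",
) -> tuple[Trajectory, BindingGroundTruth]:
    """Rigid-ligand trajectory with vMF-mixture orientations.

    Per frame a mixture component is drawn by weight and an O->C direction
    from its vMF distribution; the rigid ligand is rotated so its O->C
    vector matches the draw (hydroxyl O pinned at the cavity center).
    From ``escape_frame`` on, the ligand is additionally translated far
    outward along the escape channel so its RMSD from frame 0 stays above
    4 A permanently.  The scaffold is static.
    """
    mixture.validate()
    spec = spec or ToyComplexSpec()
    if escape_frame is not None and not (0 < escape_frame < n_frames):
        raise SpecError(
            f"escape_frame must be in (0, n_frames), got {escape_frame}"
        )
    rng = np.random.default_rng(seed)

    lig_mask = system.res_names == "LIG"
    if lig_mask.sum() != len(LIGAND_ATOM_NAMES):
        raise SpecError("system does not contain the 5-atom toy ligand")
    lig_idx = np.nonzero(lig_mask)[0]

    weights = np.array([c[3] for c in mixture.components])
    comp_ids = rng.choice(len(weights), size=n_frames, p=weights)
    directions = np.empty((n_frames, 3))
    for ci, (theta, phi, kappa, _w) in enumerate(mixture.components):
        rows = np.nonzero(comp_ids == ci)[0]
        if len(rows):
            mu = angles_to_unit(theta, phi)
            directions[rows] = sample_vmf(mu, kappa, len(rows), rng)

    escape_axis = spec.axis(escape_channel)
    coords = np.repeat(system.coords[None], n_frames, axis=0)
    thetas = np.empty(n_frames)
    phis = np.empty(n_frames)
    for f in range(n_frames):
        R = _rotation_z_to(directions[f])
        placed = LIGAND_TEMPLATE @ R.T  # O1 stays at the origin
        if escape_frame is not None and f >= escape_frame:
            shift = spec.cavity_radius + 15.0 + 0.02 * (f - escape_frame)
            placed = placed + escape_axis * shift
        coords[f, lig_idx] = placed
        thetas[f], phis[f] = unit_to_angles(directions[f])

    times = dt * np.arange(n_frames)
    truth = BindingGroundTruth(
        component_ids=comp_ids,
        thetas=thetas,
        phis=phis,
        escape_frame=escape_frame,
        escape_channel=escape_channel if escape_frame is not None else None,
    )
    return Trajectory(system=system, coords=coords, times=times), truth


def _water_system(system: MolecularSystem, n_waters: int) -> MolecularSystem:
    """Append n_waters tracer oxygens (chain W, resname HOH) to a system."""
    n0 = system.n_atoms
    return MolecularSystem(
        serials=np.concatenate([system.serials,
                                np.arange(n0 + 1, n0 + n_waters + 1)]),
        names=np.concatenate([system.names, np.array(["O"] * n_waters)]),
        elements=np.concatenate([system.elements, np.array(["O"] * n_waters)]),
        res_names=np.concatenate([system.res_names,
                                  np.array(["HOH"] * n_waters)]),
        res_ids=np.concatenate([system.res_ids,
                                np.arange(1, n_waters + 1)]),
        chain_ids=np.concatenate([system.chain_ids,
                                  np.array(["W"] * n_waters)]),
        ins_codes=np.concatenate([system.ins_codes,
                                  np.array([""] * n_waters)]),
        het_flags=np.concatenate([system.het_flags,
                                  np.ones(n_waters, dtype=bool)]),
        coords=np.vstack([system.coords, np.zeros((n_waters, 3))]),
    )


def simulate_water_trajectory(
    system: MolecularSystem,
    n_waters: int,
    event_schedule: list[ScheduledExchange | tuple],
    n_frames: int,
    dt: float = 0.1,
    flicker_prob: float = 0.0,
    flicker_max_len: int = 2,
    recovery_frames: int = 6,
    seed: int = 0,
    spec: ToyComplexSpec | None = None,
) -> tuple[Trajectory, list[ScheduledExchange]]:
    """Tracer-water trajectory realizing a scripted exchange schedule.

    Each scheduled event becomes a continuous path through its channel
    cone whose hysteresis crossing (r_in for entries, r_out for exits)
    lands exactly on the scheduled frame.  With ``flicker_prob`` > 0, a
    short (< ``flicker_max_len`` frames) spurious crossing is inserted
    ``recovery_frames`` before the real one; a downstream residence
    filter of at least ``flicker_max_len + 1`` frames suppresses it.
    Waters with no scheduled events stay in the bulk.
    """
    spec = spec or ToyComplexSpec()
    spec.validate()
    if flicker_max_len < 1:
        raise SpecError("flicker_max_len must be >= 1")
    if recovery_frames <= flicker_max_len:
        raise SpecError("recovery_frames must exceed flicker_max_len")

    events = [e if isinstance(e, ScheduledExchange) else ScheduledExchange(*e)
              for e in event_schedule]
    lead = flicker_max_len + recovery_frames + 2
    by_water: dict[int, list[ScheduledExchange]] = {}
    for ev in sorted(events, key=lambda e: (e.water_id, e.frame)):
        if ev.direction not in ("entry", "exit"):
            raise ScheduleError(f"bad direction {ev.direction!r}")
        if ev.channel not in ("A", "B"):
            raise ScheduleError(f"bad channel {ev.channel!r}")
        if not (lead <= ev.frame < n_frames):
            raise ScheduleError(
                f"scheduled frame {ev.frame} outside [{lead}, {n_frames})"
            )
        if ev.water_id < 0 or ev.water_id >= n_waters:
            raise ScheduleError(f"water id {ev.water_id} out of range")
        prev = by_water.setdefault(ev.water_id, [])
        if prev:
            if ev.frame - prev[-1].frame < 2 * flicker_max_len:
                raise ScheduleError(
                    f"events for water {ev.water_id} closer than "
                    f"2*flicker_max_len frames"
                )
            if ev.frame - prev[-1].frame < lead:
                raise ScheduleError(
                    f"events for water {ev.water_id} closer than the "
                    f"{lead}-frame path length"
                )
            if ev.direction == prev[-1].direction:
                raise ScheduleError(
                    f"water {ev.water_id} has two consecutive "
                    f"{ev.direction} events"
                )
        prev.append(ev)

    rng = np.random.default_rng(seed)
    full = _water_system(system, n_waters)
    water_idx = np.arange(system.n_atoms, system.n_atoms + n_waters)
    coords = np.repeat(full.coords[None], n_frames, axis=0)

    r_mid = 0.5 * (spec.r_in + spec.r_out)
    r_inside = 1.0
    r_outside = spec.r_out + 4.0

    def inside_pos(axis: np.ndarray) -> np.ndarray:
        return axis * r_inside

    def outside_pos(axis: np.ndarray) -> np.ndarray:
        return axis * r_outside

    bulk_dirs = sample_vmf(np.array([0.0, 0.0, 1.0]), 0.0, n_waters, rng)
    for w in range(n_waters):
        wev = by_water.get(w, [])
        axis0 = spec.axis(wev[0].channel) if wev else bulk_dirs[w]
        if wev and wev[0].direction == "entry":
            pos = outside_pos(axis0)
        elif wev:
            pos = inside_pos(axis0)
        else:
            pos = bulk_dirs[w] * (spec.cavity_radius + 6.0)
        path = np.repeat(pos[None], n_frames, axis=0)

        for ev in wev:
            axis = spec.axis(ev.channel)
            f = ev.frame
            if ev.direction == "exit":
                before, after = inside_pos(axis), outside_pos(axis)
                flick_r, mid_r = r_outside, r_mid
            else:
                before, after = outside_pos(axis), inside_pos(axis)
                flick_r, mid_r = r_inside, r_mid
            path[f - lead:f] = before
            # spurious pre-crossing, suppressed by the residence filter
            if flicker_prob > 0 and rng.random() < flicker_prob:
                flen = int(rng.integers(1, flicker_max_len + 1))
                g = f - recovery_frames - flen
                path[g:g + flen] = axis * flick_r
            path[f - 1] = axis * mid_r      # dead band: no state change
            path[f:] = after

        coords[:, water_idx[w]] = path

    times = dt * np.arange(n_frames)
    traj = Trajectory(system=full, coords=coords, times=times)
    return traj, sorted(events, key=lambda e: (e.frame, e.water_id))
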