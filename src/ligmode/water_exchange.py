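"""Cavity water-exchange detection with hysteresis and channel labels.

Cavity membership is radial with hysteresis around the per-frame centroid
of the cavity-lining atoms: a water becomes *inside* when its distance to
the center drops to R_in or below, and *outside* when it reaches R_out or
above; between the radii the previous state is kept (dead band).  State
stretches shorter than a residence filter are merged into their
surroundings before entry/exit events are emitted, suppressing thermal
boundary flicker.  Each event is assigned to the entrance channel whose
gate-residue centroid is nearest to the water oxygen at the crossing
frame.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigError, UsageError
from .trajio import Selection, Trajectory

__all__ = [
    "CavityDefinition",
    "ExchangeEvent",
    "ExchangeSummary",
    "occupancy_series",
    "detect_exchange_events",
    "assign_channels",
    "channel_fractions",
]


def _indices(sel) -> np.ndarray:
    return np.asarray(getattr(sel, "indices", sel), dtype=np.intp)


@dataclass
class CavityDefinition:
    """Lining atoms define the moving center; R_in/R_out the hysteresis."""

    lining: Selection | np.ndarray
    r_in: float
    r_out: float

    def __post_init__(self) -> None:
        if len(_indices(self.lining)) == 0:
            raise ConfigError("cavity lining selection is empty")
        if self.r_out <= self.r_in:
            raise ConfigError("R_out must exceed R_in")
        if self.r_out - self.r_in < 0.5:
            raise ConfigError("hysteresis band R_out - R_in must be >= 0.5 A")

    def centers(self, traj: Trajectory) -> np.ndarray:
        lin = _indices(self.lining)
        return traj.coords[:, lin].mean(axis=1)


@dataclass(frozen=True)
class ExchangeEvent:
    """One water crossing of the cavity boundary."""

    water_id: int          # index into the water selection order
    atom_index: int        # topology atom index of the water oxygen
    frame: int             # first frame in the new state
    direction: str         # "entry" | "exit"
    channel: str = "unassigned"   # "A" | "B" | "unassigned"
    gate_distance: float = float("nan")  # distance to winning gate centroid


def occupancy_series(traj: Trajectory, cavity: CavityDefinition,
                     water_selection: Selection | np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Hysteretic per-water inside/outside series.

    Returns (occupancy, atom_indices) where occupancy is a boolean
    (n_waters, n_frames) array (True = inside).  The initial state is
    taken from the frame-0 distance against the band midpoint.
    """
    waters = _indices(water_selection)
    if len(waters) == 0:
        raise UsageError("water selection is empty")
    centers = cavity.centers(traj)
    # (n_waters, n_frames) distances to the moving center
    d = np.linalg.norm(
        traj.coords[:, waters].transpose(1, 0, 2) - centers[None], axis=2
    )
    mid = 0.5 * (cavity.r_in + cavity.r_out)
    occ = np.empty_like(d, dtype=bool)
    state = d[:, 0] < mid
    for f in range(traj.n_frames):
        state = np.where(d[:, f] <= cavity.r_in, True,
                         np.where(d[:, f] >= cavity.r_out, False, state))
        occ[:, f] = state
    return occ, waters


def _merge_short_runs(states: np.ndarray, min_len: int) -> list[tuple[bool, int, int]]:
    """Run-length encode a boolean series and merge interior runs shorter
    than ``min_len`` into their (identical-state) surroundings.

    The first and last runs are never merged away -- their true extent is
    unknowable at the series boundaries.  Among mergeable runs the
    shortest (earliest on ties) is merged first, then runs re-coalesce.
    Returns the final list of (state, start_frame, length).
    """
    runs: list[list] = []
    for f, s in enumerate(states):
        if runs and runs[-1][0] == s:
            runs[-1][2] += 1
        else:
            runs.append([bool(s), f, 1])
    while True:
        candidates = [
            (runs[i][2], i) for i in range(1, len(runs) - 1)
            if runs[i][2] < min_len
        ]
        if not candidates:
            break
        _, i = min(candidates)
        runs[i][0] = runs[i - 1][0]
        merged = [runs[0]]
        for run in runs[1:]:
            if run[0] == merged[-1][0]:
                merged[-1][2] += run[2]
            else:
                merged.append(run)
        runs = merged
    return [(r[0], r[1], r[2]) for r in runs]


def detect_exchange_events(occupancy: np.ndarray,
                           atom_indices: np.ndarray | None = None,
                           min_residence_frames: int = 5
                           ) -> list[ExchangeEvent]:
    """Entry/exit events from hysteretic occupancy, flicker-filtered.

    State stretches shorter than ``min_residence_frames`` are merged into
    the surrounding state first; each surviving transition yields one
    event carrying the first frame of the new state.
    """
    if min_residence_frames < 1:
        raise UsageError("min_residence_frames must be >= 1")
    occupancy = np.asarray(occupancy, dtype=bool)
    if occupancy.ndim != 2:
        raise UsageError("occupancy must be a (n_waters, n_frames) array")
    if atom_indices is None:
        atom_indices = np.arange(occupancy.shape[0])
    events: list[ExchangeEvent] = []
    for w in range(occupancy.shape[0]):
        runs = _merge_short_runs(occupancy[w], min_residence_frames)
        for prev, cur in zip(runs[:-1], runs[1:]):
            direction = "entry" if cur[0] else "exit"
            events.append(ExchangeEvent(
                water_id=w, atom_index=int(atom_indices[w]),
                frame=cur[1], direction=direction,
            ))
    events.sort(key=lambda e: (e.frame, e.water_id))
    return events


def assign_channels(events: list[ExchangeEvent], traj: Trajectory,
                    gate_a_selection: Selection | np.ndarray,
                    gate_b_selection: Selection | np.ndarray,
                    tie_tolerance: float = 0.01,
                    path_window: int = 0) -> list[ExchangeEvent]:
    """Label each event with the nearer gate (A or B) at its crossing frame.

    Gates are compared by the distance from the water oxygen to each
    gate's heavy-atom centroid; differences below ``tie_tolerance``
    leave the event unassigned.  ``path_window`` > 0 switches to a
    majority vote of the per-frame nearest gate over the frames within
    +/- path_window of the crossing.
    """
    ga = _indices(gate_a_selection)
    gb = _indices(gate_b_selection)
    if len(ga) == 0 and len(gb) == 0:
        raise UsageError("both gate selections are empty")
    if len(ga) == 0 or len(gb) == 0:
        raise UsageError("gate selections must both be nonempty")
    if set(ga.tolist()) & set(gb.tolist()):
        raise UsageError("gate selections must be disjoint")

    heavy = traj.system.heavy_mask()
    ga = ga[heavy[ga]]
    gb = gb[heavy[gb]]

    out: list[ExchangeEvent] = []
    for ev in events:
        frames = [ev.frame]
        if path_window > 0:
            frames = [f for f in range(ev.frame - path_window,
                                       ev.frame + path_window + 1)
                      if 0 <= f < traj.n_frames]
        votes = {"A": 0, "B": 0}
        dist_at_crossing = {"A": np.nan, "B": np.nan}
        for f in frames:
            pos = traj.coords[f, ev.atom_index]
            da = float(np.linalg.norm(traj.coords[f, ga].mean(axis=0) - pos))
            db = float(np.linalg.norm(traj.coords[f, gb].mean(axis=0) - pos))
            if f == ev.frame:
                dist_at_crossing = {"A": da, "B": db}
            if abs(da - db) < tie_tolerance:
                continue
            votes["A" if da < db else "B"] += 1
        if votes["A"] == votes["B"]:
            label, gd = "unassigned", float("nan")
        else:
            label = "A" if votes["A"] > votes["B"] else "B"
            gd = dist_at_crossing[label]
        out.append(replace(ev, channel=label, gate_distance=gd))
    return out


@dataclass
class ExchangeSummary:
    n_events: int
    n_entries: int
    n_exits: int
    n_unique_waters: int
    n_assigned: int
    n_unassigned: int
    fraction_a: float
    fraction_b: float


def channel_fractions(events: list[ExchangeEvent]) -> ExchangeSummary:
    """Event counts and per-channel fractions over assigned events.

    Both the event count and the unique-water count are reported, since
    an 'exchanged waters' total may mean either.
    """
    n_a = sum(1 for e in events if e.channel == "A")
    n_b = sum(1 for e in events if e.channel == "B")
    assigned = n_a + n_b
    return ExchangeSummary(
        n_events=len(events),
        n_entries=sum(1 for e in events if e.direction == "entry"),
        n_exits=sum(1 for e in events if e.direction == "exit"),
        n_unique_waters=len({e.water_id for e in events}),
        n_assigned=assigned,
        n_unassigned=len(events) - assigned,
        fraction_a=n_a / assigned if assigned else float("nan"),
        fraction_b=n_b / assigned if assigned else float("nan"),
    )
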