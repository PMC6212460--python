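"""Ligand-RMSD series and first-passage escape-time statistics.

A replica "escapes" at the first frame whose ligand heavy-atom RMSD from
the initial geometry reaches a threshold (default 4 A), after a global
fit of each frame onto the reference frame over the protein CA atoms.
Replicas that never reach the threshold are censored at their total
simulated time; censored values rank above every observed value in the
order statistics (the only ranking consistent with reporting a finite
median when nearly half the replicas are censored).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UsageError
from .trajio import Selection, Trajectory, rmsd, superpose

__all__ = [
    "EscapeRecord",
    "EscapeSummary",
    "ligand_rmsd_series",
    "escape_time",
    "escape_statistics",
]


@dataclass(frozen=True)
class EscapeRecord:
    """First-passage result for one replica."""

    replica_id: str
    escape_time: float | None   # ns; None when censored
    censored: bool
    threshold: float            # A
    total_time: float           # ns

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise UsageError("threshold must be > 0")
        if not self.censored and self.escape_time is not None:
            if self.escape_time > self.total_time + 1e-9:
                raise UsageError("escape_time exceeds total simulated time")

    @property
    def rank_value(self) -> float:
        """Value used for order statistics; censored dominates observed."""
        return np.inf if self.censored else float(self.escape_time)


def _indices(sel) -> np.ndarray:
    return np.asarray(getattr(sel, "indices", sel), dtype=np.intp)


def ligand_rmsd_series(traj: Trajectory,
                       ligand_selection: Selection | np.ndarray,
                       fit_selection: Selection | np.ndarray,
                       reference_frame: int = 0) -> np.ndarray:
    """Per-frame ligand RMSD from ``reference_frame`` after a global fit.

    Each frame is superposed on the reference frame over
    ``fit_selection`` (typically protein CA atoms); the RMSD is then
    taken over the ligand selection without refitting.
    """
    if not (0 <= reference_frame < traj.n_frames):
        raise UsageError(
            f"reference_frame {reference_frame} outside [0, {traj.n_frames})"
        )
    lig = _indices(ligand_selection)
    fit = _indices(fit_selection)
    if len(lig) == 0 or len(fit) == 0:
        raise UsageError("ligand and fit selections must be nonempty")
    ref = traj.coords[reference_frame]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        moved, _ = superpose(traj.coords[f], ref, fit)
        out[f] = rmsd(moved[lig], ref[lig])
    return out


def escape_time(series: np.ndarray, dt: float, threshold: float = 4.0,
                persistence: int = 1, replica_id: str = "",
                t0: float = 0.0) -> EscapeRecord:
    """First-passage time at which the series reaches ``threshold``.

    The crossing is inclusive (>=).  ``persistence`` > 1 requires that
    many consecutive frames at or above the threshold (for noisy data);
    the reported time is that of the first frame of the qualifying run.
    Censored at the last frame's time when the threshold is never met.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.size == 0:
        raise UsageError("empty RMSD series")
    if dt <= 0:
        raise UsageError("dt must be > 0")
    if persistence < 1:
        raise UsageError("persistence must be >= 1")
    total = t0 + dt * (len(series) - 1)
    above = series >= threshold
    run = 0
    for f, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= persistence:
            first = f - persistence + 1
            return EscapeRecord(replica_id=replica_id,
                                escape_time=t0 + first * dt, censored=False,
                                threshold=threshold, total_time=total)
    return EscapeRecord(replica_id=replica_id, escape_time=None,
                        censored=True, threshold=threshold, total_time=total)


@dataclass
class EscapeSummary:
    """Rank-based summary over replicas; censored quantiles are None and
    reported as '>= total time'."""

    n_total: int
    n_censored: int
    threshold: float
    total_time: float
    median: float | None
    q1: float | None
    q3: float | None

    def describe(self, which: str = "median") -> str:
        value = getattr(self, which)
        if value is None:
            return f">= {self.total_time:g} ns (censored)"
        return f"{value:g} ns"


def _rank_quantile(values: np.ndarray, idx: int) -> float | None:
    v = values[idx]
    return None if np.isinf(v) else float(v)


def escape_statistics(records: list[EscapeRecord]) -> EscapeSummary:
    """Median and quartiles by rank, with censored records ranked last.

    For an even count the median is the lower-middle value when both
    middle ranks are observed, else censored.  Quartiles use the lower
    order statistic at rank floor(q * (n - 1)).
    """
    if not records:
        raise UsageError("no escape records")
    thresholds = {r.threshold for r in records}
    if len(thresholds) > 1:
        raise UsageError(f"mixed thresholds in records: {sorted(thresholds)}")
    values = np.sort([r.rank_value for r in records])
    n = len(values)
    total = max(r.total_time for r in records)

    if n % 2 == 1:
        median = _rank_quantile(values, n // 2)
    else:
        lo, hi = values[n // 2 - 1], values[n // 2]
        median = float(lo) if (np.isfinite(lo) and np.isfinite(hi)) else None

    q1 = _rank_quantile(values, int(0.25 * (n - 1)))
    q3 = _rank_quantile(values, int(0.75 * (n - 1)))
    return EscapeSummary(
        n_total=n,
        n_censored=int(sum(r.censored for r in records)),
        threshold=records[0].threshold,
        total_time=total,
        median=median,
        q1=q1,
        q3=q3,
    )
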