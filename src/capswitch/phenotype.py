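"""Phenotype-level summaries of CAP trajectories.

A cell is called Cap+ (``CAP_HIGH``) while its CAP count exceeds a
threshold and Cap- (``CAP_LOW``) otherwise.  The threshold is either given
explicitly or chosen from the time-weighted CAP histogram: when the
histogram is bimodal the threshold is the midpoint between the two largest
modes; otherwise a fixed fallback of 20 molecules is used (below the
~100-molecule extreme of the high-production regime).  The threshold used
is always recorded in the output, because every occupancy number downstream
depends on it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "CAP_LOW",
    "CAP_HIGH",
    "FALLBACK_THRESHOLD",
    "PhenotypeSegments",
    "OccupancySummary",
    "choose_threshold",
    "classify_states",
    "occupancy_summary",
    "cumulative_occupancy_curve",
    "heritability_proxy",
]

CAP_LOW = "CAP_LOW"
CAP_HIGH = "CAP_HIGH"

#: Fixed state-call threshold (CAP molecules) used when the time-weighted
#: CAP histogram is not clearly bimodal.
FALLBACK_THRESHOLD = 20.0

#: Minimal mode separation (molecules) for the histogram to count as bimodal.
_MIN_MODE_SEPARATION = 10


@dataclass
class PhenotypeSegments:
    """Alternating Cap-/Cap+ intervals tiling the analysis window exactly."""

    segments: List[Tuple[float, float, str]]
    threshold: float
    source_id: str

    def __post_init__(self) -> None:
        for i, (a, b, s) in enumerate(self.segments):
            if not b > a:
                raise ValueError(f"degenerate segment {i}: ({a}, {b})")
            if s not in (CAP_LOW, CAP_HIGH):
                raise ValueError(f"unknown state {s!r}")
            if i:
                pa, pb, ps = self.segments[i - 1]
                if abs(pb - a) > 1e-9:
                    raise ValueError("segments must tile the window without gaps")
                if ps == s:
                    raise ValueError("adjacent segments must differ in state")

    @property
    def window(self) -> Tuple[float, float]:
        return (self.segments[0][0], self.segments[-1][1])

    def dwell_times(self, state: str) -> np.ndarray:
        return np.array([b - a for a, b, s in self.segments if s == state])

    def n_switches(self) -> int:
        return len(self.segments) - 1

    def write_tsv(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            fh.write(f"# threshold_molecules={self.threshold}\tsource={self.source_id}\n")
            fh.write("start_s\tend_s\tstate\n")
            for a, b, s in self.segments:
                fh.write(f"{float(a)!r}\t{float(b)!r}\t{s}\n")


@dataclass
class OccupancySummary:
    """Time-weighted phenotype statistics for one trajectory."""

    fraction_cap_low: float
    fraction_cap_high: float
    mean_dwell_low_s: float   # nan when the state was never visited
    mean_dwell_high_s: float
    n_switches: int
    mean_cap_low: float       # time-weighted mean CAP level within the state
    mean_cap_high: float
    threshold: float

    def to_dict(self) -> Dict[str, float]:
        return dict(self.__dict__)


def _cap_series(traj) -> Tuple[np.ndarray, np.ndarray, float, float]:
    if "CA" not in traj.species:
        raise ValueError("trajectory does not contain the CA (CAP) species")
    t0, t1 = traj.window
    return traj.times, traj.series("CA"), t0, t1


def _interval_durations(times: np.ndarray, t_end: float) -> np.ndarray:
    """Duration each record's state prevails (sample-and-hold to t_end)."""
    return np.diff(np.append(times, t_end))


def choose_threshold(traj) -> float:
    """Data-driven state-call threshold from the time-weighted CAP histogram.

    Bimodal histogram: midpoint of the two heaviest well-separated modes.
    Unimodal (or ambiguous): :data:`FALLBACK_THRESHOLD`.
    """
    times, cap, t0, t1 = _cap_series(traj)
    dur = _interval_durations(times, t1)
    hi = int(cap.max())
    if hi == 0:
        return FALLBACK_THRESHOLD
    weights = np.bincount(cap.astype(np.int64), weights=dur, minlength=hi + 1)
    # smooth with a short moving average so shot noise does not split modes
    w = 5
    kernel = np.ones(w) / w
    smooth = np.convolve(weights, kernel, mode="same")
    # local maxima with non-trivial mass
    total = smooth.sum()
    peaks = []
    for i in range(len(smooth)):
        left = smooth[i - 1] if i > 0 else -1.0
        right = smooth[i + 1] if i < len(smooth) - 1 else -1.0
        if smooth[i] > left and smooth[i] >= right and smooth[i] > 0.005 * total:
            peaks.append((smooth[i], i))
    peaks.sort(reverse=True)
    if len(peaks) >= 2:
        # the two heaviest modes, provided they are genuinely separated by a valley
        (w1, m1), (w2, m2) = peaks[0], peaks[1]
        lo_m, hi_m = sorted((m1, m2))
        if hi_m - lo_m >= _MIN_MODE_SEPARATION:
            valley = smooth[lo_m:hi_m + 1].min()
            if valley < 0.5 * min(w1, w2):
                return (lo_m + hi_m) / 2.0
    return FALLBACK_THRESHOLD


def classify_states(traj, threshold: Optional[float] = None) -> PhenotypeSegments:
    """Call Cap-/Cap+ states along a trajectory.

    CAP > *threshold* is ``CAP_HIGH``, else ``CAP_LOW``; contiguous
    same-state intervals are merged so that segments tile the post-burn-in
    window exactly.  When *threshold* is None it is chosen by
    :func:`choose_threshold`.
    """
    if threshold is None:
        threshold = choose_threshold(traj)
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    times, cap, t0, t1 = _cap_series(traj)
    states = np.where(cap > threshold, 1, 0)
    segments: List[Tuple[float, float, str]] = []
    seg_start = t0
    cur = states[0]
    for i in range(1, len(states)):
        if states[i] != cur:
            segments.append((seg_start, times[i], _name(cur)))
            seg_start = times[i]
            cur = states[i]
    if t1 > seg_start:
        segments.append((seg_start, t1, _name(cur)))
    elif not segments:
        raise ValueError("empty analysis window")
    return PhenotypeSegments(segments=segments, threshold=float(threshold),
                             source_id=traj.traj_id)


def _name(flag: int) -> str:
    return CAP_HIGH if flag else CAP_LOW


def occupancy_summary(segs: PhenotypeSegments, traj) -> OccupancySummary:
    """Time-weighted occupancy/dwell statistics for *segs* over *traj*."""
    if segs.source_id != traj.traj_id:
        raise ValueError(
            f"segments derive from {segs.source_id!r}, not {traj.traj_id!r}"
        )
    t0, t1 = segs.window
    window = t1 - t0
    dwell_low = segs.dwell_times(CAP_LOW)
    dwell_high = segs.dwell_times(CAP_HIGH)
    frac_low = dwell_low.sum() / window
    # time-weighted mean CAP level within each state
    times, cap, _, traj_t1 = _cap_series(traj)
    dur = _interval_durations(times, traj_t1)
    state_flags = cap > segs.threshold
    t_low = dur[~state_flags].sum()
    t_high = dur[state_flags].sum()
    mean_low = float((cap[~state_flags] * dur[~state_flags]).sum() / t_low) if t_low else float("nan")
    mean_high = float((cap[state_flags] * dur[state_flags]).sum() / t_high) if t_high else float("nan")
    return OccupancySummary(
        fraction_cap_low=float(frac_low),
        fraction_cap_high=float(1.0 - frac_low),
        mean_dwell_low_s=float(dwell_low.mean()) if dwell_low.size else float("nan"),
        mean_dwell_high_s=float(dwell_high.mean()) if dwell_high.size else float("nan"),
        n_switches=segs.n_switches(),
        mean_cap_low=mean_low,
        mean_cap_high=mean_high,
        threshold=segs.threshold,
    )


def cumulative_occupancy_curve(traj, levels: Sequence[float]) -> np.ndarray:
    """Cumulative time spent at each CAP level or below.

    Returns an array of shape (len(levels), 2): column 0 the level, column 1
    the total time with CAP <= level within the analysis window.  The curve
    is monotone non-decreasing and reaches the window duration at (and
    beyond) the maximum observed CAP level.
    """
    levels = np.asarray(levels, dtype=np.float64)
    if levels.size == 0:
        raise ValueError("levels must be non-empty")
    if np.any(np.diff(levels) < 0):
        raise ValueError("levels must be ascending")
    if np.any(levels < 0):
        raise ValueError("levels must be non-negative")
    times, cap, t0, t1 = _cap_series(traj)
    dur = _interval_durations(times, t1)
    order = np.argsort(cap, kind="stable")
    cap_sorted = cap[order]
    cum = np.cumsum(dur[order])
    idx = np.searchsorted(cap_sorted, levels, side="right")
    cum_time = np.where(idx > 0, cum[np.maximum(idx - 1, 0)], 0.0)
    return np.column_stack([levels, cum_time])


def heritability_proxy(segs: PhenotypeSegments, division_time: float = 3600.0
                       ) -> Dict[str, float]:
    """Mean dwell time per state expressed in cell-division equivalents.

    ``division_time`` defaults to 3600 s, matching the ~60 min division
    times observed for both phenotypes.  States never visited map to nan.
    """
    if not division_time > 0:
        raise ValueError("division_time must be > 0")
    if not segs.segments:
        raise ValueError("no segments")
    out = {}
    for state in (CAP_LOW, CAP_HIGH):
        d = segs.dwell_times(state)
        out[state] = float(d.mean() / division_time) if d.size else float("nan")
    return out


def write_curve_tsv(curve: np.ndarray, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("level\tcumulative_seconds\n")
        for lvl, sec in curve:
            fh.write(f"{float(lvl)!r}\t{float(sec)!r}\n")
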