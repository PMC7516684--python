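"""Gait-phase segmentation from plantar-pressure and IMU streams.

The phase rule follows the activated-sensor-count convention: a pressure
channel is *activated* when its (median-filtered) value is at or above
the activation threshold (default 4.3 N/cm^2); a frame with zero
activated channels is swing, a frame with one or more is stance.  With
both feet segmented, frames where both feet are in stance are double
support, frames with exactly one stance foot are single support, and
both-feet-swing frames (physiologically impossible in walking) are
flagged as ``none`` and excluded from support statistics.

TUG sub-phases (sit-to-stand, walking, total TUG) are derived from the
summed bilateral pressure relative to the seated baseline and the
standing plateau; per-cycle stride lengths come from zero-velocity-
update (ZUPT) corrected double integration of the gravity-free forward
acceleration axis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .errors import AlignmentError, ConfigError, DataValidationError, SegmentationError


@dataclass
class SegmentationConfig:
    """Tunables for phase detection and TUG sub-phase derivation.

    ``activation_threshold_Ncm2`` is the per-channel pressure at or above
    which a sensor counts as activated.  ``median_filter_width_samples``
    is the per-channel running-median width (odd; 5 samples = 50 ms at
    100 Hz).  Phases shorter than ``min_phase_duration_s`` are treated as
    sensor chatter and merged into their neighbours.
    """

    activation_threshold_Ncm2: float = 4.3
    median_filter_width_samples: int = 5
    min_phase_duration_s: float = 0.06
    sit_baseline_window_s: float = 1.0
    stand_plateau_fraction: float = 0.9
    sit_to_stand_onset_fraction: float = 0.25
    sustained_s: float = 0.3

    def __post_init__(self) -> None:
        if not (self.activation_threshold_Ncm2 > 0):
            raise ConfigError("activation threshold must be positive")
        w = self.median_filter_width_samples
        if w < 1 or w % 2 == 0:
            raise ConfigError("median filter width must be an odd integer >= 1")
        if self.min_phase_duration_s < 0:
            raise ConfigError("min_phase_duration_s must be >= 0")
        for name in ("stand_plateau_fraction", "sit_to_stand_onset_fraction"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ConfigError(f"{name} must lie in (0, 1)")
        if self.sit_baseline_window_s <= 0 or self.sustained_s < 0:
            raise ConfigError("window durations must be positive")


@dataclass(frozen=True)
class PhaseInterval:
    """A maximal swing or stance run of one foot, half-open in samples."""

    side: str
    phase: str  # "stance" | "swing"
    start_idx: int
    end_idx: int
    fs: float

    @property
    def duration_s(self) -> float:
        return (self.end_idx - self.start_idx) / self.fs


@dataclass(frozen=True)
class SupportInterval:
    """Bilateral support state over a maximal sample run."""

    kind: str  # "single_left" | "single_right" | "double" | "none"
    start_idx: int
    end_idx: int


@dataclass
class GaitCycle:
    """Stance-onset-to-stance-onset cycle of one foot."""

    side: str
    start_idx: int
    end_idx: int
    stance_s: float
    swing_s: float
    cycle_s: float
    stride_length_m: Optional[float] = None
    stride_clamped: bool = False


@dataclass
class TUGSegmentation:
    """TUG sub-phase windows (seconds from trial start) and step count."""

    sit_to_stand: tuple[float, float]
    walking: tuple[float, float]
    tug: tuple[float, float]
    step_count: int

    def __post_init__(self) -> None:
        s2s, walk, tug = self.sit_to_stand, self.walking, self.tug
        if not (tug[0] <= s2s[0] and s2s[1] <= tug[1]):
            raise SegmentationError("sit_to_stand window must lie inside the TUG window")
        if not (tug[0] <= walk[0] and walk[1] <= tug[1]):
            raise SegmentationError("walking window must lie inside the TUG window")
        if s2s[1] > walk[0]:
            raise SegmentationError("sit-to-stand must end before walking starts")

    @property
    def tug_time_s(self) -> float:
        return self.tug[1] - self.tug[0]

    @property
    def walking_time_s(self) -> float:
        return self.walking[1] - self.walking[0]

    @property
    def sit_to_stand_s(self) -> float:
        return self.sit_to_stand[1] - self.sit_to_stand[0]


# ---------------------------------------------------------------------------
# filtering and activation counting
# ---------------------------------------------------------------------------


def median_filter_columns(x: np.ndarray, width: int) -> np.ndarray:
    """Per-column running median; edge windows shrink to the available samples."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if width == 1 or n == 0:
        return x.copy()
    if n < width:
        raise DataValidationError(
            f"series of {n} samples shorter than filter width {width}"
        )
    half = width // 2
    out = np.empty_like(x)
    windows = np.lib.stride_tricks.sliding_window_view(x, width, axis=0)
    out[half : n - half] = np.median(windows, axis=-1)
    for i in range(half):
        out[i] = np.median(x[: i + half + 1], axis=0)
        out[n - 1 - i] = np.median(x[n - 1 - i - half :], axis=0)
    return out


def preprocess_and_count(rec, cfg: SegmentationConfig = SegmentationConfig()) -> np.ndarray:
    """Median-filter each pressure channel and count activated channels per frame.

    A channel is activated when its filtered value is at or above the
    threshold (inclusive, "4.3 N/cm^2 or more").  Returns an integer
    series in 0..8.
    """
    filtered = median_filter_columns(rec.pressure, cfg.median_filter_width_samples)
    return (filtered >= cfg.activation_threshold_Ncm2).sum(axis=1).astype(np.int64)


# ---------------------------------------------------------------------------
# phase detection
# ---------------------------------------------------------------------------


def _runs(mask: np.ndarray) -> list[tuple[int, int, bool]]:
    """Maximal runs of a boolean series as (start, end, value)."""
    n = len(mask)
    if n == 0:
        return []
    change = np.flatnonzero(np.diff(mask.astype(np.int8))) + 1
    bounds = np.concatenate(([0], change, [n]))
    return [(int(a), int(b), bool(mask[a])) for a, b in zip(bounds[:-1], bounds[1:])]


def _merge_short_runs(runs: list[list], min_samples: float) -> list[list]:
    """Repeatedly absorb the shortest sub-threshold run into its neighbours.

    Interior runs merge their two (same-phase) neighbours into one; edge
    runs are absorbed by their single neighbour.  Ties pick the earliest
    (preceding) run first.
    """
    runs = [list(r) for r in runs]
    while len(runs) > 1:
        durations = [r[1] - r[0] for r in runs]
        short = [i for i, d in enumerate(durations) if d < min_samples]
        if not short:
            break
        i = min(short, key=lambda j: (durations[j], j))
        if i == 0:
            runs[1][0] = runs[0][0]
            del runs[0]
        elif i == len(runs) - 1:
            runs[-2][1] = runs[-1][1]
            del runs[-1]
        else:
            runs[i - 1][1] = runs[i + 1][1]
            del runs[i : i + 2]
    return runs


def detect_phases(counts: np.ndarray, fs: float,
                  cfg: SegmentationConfig = SegmentationConfig(),
                  side: str = "left") -> list[PhaseInterval]:
    """Swing/stance intervals from the activated-sensor count series.

    Swing = maximal run of count 0, stance = maximal run of count > 0,
    then debouncing: runs shorter than ``min_phase_duration_s`` are merged
    into the surrounding phase.  The result alternates and tiles [0, n).
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        raise DataValidationError("counts series is empty")
    runs = [[a, b, v] for a, b, v in _runs(counts > 0)]
    runs = _merge_short_runs(runs, cfg.min_phase_duration_s * fs)
    return [
        PhaseInterval(side=side, phase="stance" if v else "swing",
                      start_idx=a, end_idx=b, fs=fs)
        for a, b, v in runs
    ]


# ---------------------------------------------------------------------------
# bilateral support classification
# ---------------------------------------------------------------------------

_SUPPORT_KIND = {
    (True, True): "double",
    (True, False): "single_left",
    (False, True): "single_right",
    (False, False): "none",
}


def _check_tiling(phases: Sequence[PhaseInterval]) -> tuple[int, int]:
    if not phases:
        raise AlignmentError("empty phase list")
    start, end = phases[0].start_idx, phases[-1].end_idx
    pos = start
    for p in phases:
        if p.start_idx != pos or p.end_idx <= p.start_idx:
            raise AlignmentError("phase intervals do not tile the window")
        pos = p.end_idx
    return start, end


def classify_support(phases_left: Sequence[PhaseInterval],
                     phases_right: Sequence[PhaseInterval]) -> list[SupportInterval]:
    """Partition the common window into single/double/none support intervals.

    Event-sweep over the union of phase boundaries; output intervals are
    maximal (adjacent equal kinds merged).
    """
    wl = _check_tiling(phases_left)
    wr = _check_tiling(phases_right)
    if wl != wr:
        raise AlignmentError(f"phase windows differ: left {wl} vs right {wr}")

    def stance_at(phases: Sequence[PhaseInterval], starts: np.ndarray, t: int) -> bool:
        i = int(np.searchsorted(starts, t, side="right")) - 1
        return phases[i].phase == "stance"

    starts_l = np.array([p.start_idx for p in phases_left])
    starts_r = np.array([p.start_idx for p in phases_right])
    bounds = sorted(
        {p.start_idx for p in phases_left}
        | {p.start_idx for p in phases_right}
        | {wl[1]}
    )
    out: list[SupportInterval] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        kind = _SUPPORT_KIND[
            (stance_at(phases_left, starts_l, a), stance_at(phases_right, starts_r, a))
        ]
        if out and out[-1].kind == kind:
            out[-1] = SupportInterval(kind, out[-1].start_idx, b)
        else:
            out.append(SupportInterval(kind, a, b))
    return out


# ---------------------------------------------------------------------------
# cycle extraction
# ---------------------------------------------------------------------------


def extract_cycles(phases: Sequence[PhaseInterval]) -> list[GaitCycle]:
    """One cycle per (stance, following swing) pair, stance onset to next onset.

    Leading swing and trailing unpaired intervals are dropped; fewer than
    two stance intervals yield an empty list.
    """
    cycles: list[GaitCycle] = []
    for i, p in enumerate(phases):
        if (
            p.phase == "stance"
            and i + 2 < len(phases)
            and phases[i + 1].phase == "swing"
            and phases[i + 2].phase == "stance"
        ):
            nxt = phases[i + 2]
            cycles.append(
                GaitCycle(
                    side=p.side,
                    start_idx=p.start_idx,
                    end_idx=nxt.start_idx,
                    stance_s=p.duration_s,
                    swing_s=phases[i + 1].duration_s,
                    cycle_s=(nxt.start_idx - p.start_idx) / p.fs,
                )
            )
    return cycles


# ---------------------------------------------------------------------------
# TUG sub-phase segmentation
# ---------------------------------------------------------------------------


def _first_sustained(mask: np.ndarray, m: int, start: int = 0) -> Optional[int]:
    """First index >= start where ``mask`` holds for m consecutive frames."""
    m = max(m, 1)
    sub = mask[start:]
    if len(sub) < m:
        return None
    windows = np.lib.stride_tricks.sliding_window_view(sub, m)
    hits = np.flatnonzero(windows.all(axis=1))
    return int(hits[0]) + start if hits.size else None


def _stance_mask(phases: Sequence[PhaseInterval], n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for p in phases:
        if p.phase == "stance":
            mask[p.start_idx : p.end_idx] = True
    return mask


def segment_tug(trial, phases_left: Sequence[PhaseInterval],
                phases_right: Sequence[PhaseInterval],
                cfg: SegmentationConfig = SegmentationConfig()) -> TUGSegmentation:
    """Derive sit-to-stand, walking and total-TUG windows plus step count.

    Seated baseline and standing plateau are medians of the summed
    bilateral (filtered) pressure; the rising/falling landmarks are
    threshold crossings sustained for ``cfg.sustained_s``.
    """
    trial = trial.aligned()
    n = trial.n_samples
    fs = trial.fs
    total = (
        median_filter_columns(trial.left.pressure, cfg.median_filter_width_samples).sum(axis=1)
        + median_filter_columns(trial.right.pressure, cfg.median_filter_width_samples).sum(axis=1)
    )

    # real swing intervals: exclude each foot's leading/trailing (seated) runs
    swing_starts: list[int] = []
    stance_onsets: list[int] = []
    for phases in (phases_left, phases_right):
        for i, p in enumerate(phases):
            if p.phase == "swing" and 0 < i < len(phases) - 1:
                swing_starts.append(p.start_idx)
            if p.phase == "stance" and i > 0:
                stance_onsets.append(p.start_idx)
    if not swing_starts:
        raise SegmentationError("no swing phase detected: trial contains no gait")

    first_swing = min(swing_starts)
    last_onset = max(stance_onsets)
    both_stance = _stance_mask(phases_left, n) & _stance_mask(phases_right, n)
    walk_double = both_stance.copy()
    walk_double[:first_swing] = False
    walk_double[last_onset:] = False
    if not walk_double.any():
        raise SegmentationError("no double-support frames in the walking region")

    baseline = float(np.median(total[: max(1, round(cfg.sit_baseline_window_s * fs))]))
    plateau = float(np.median(total[walk_double]))
    if plateau <= baseline:
        raise SegmentationError("standing plateau does not exceed seated baseline")
    low = baseline + cfg.sit_to_stand_onset_fraction * (plateau - baseline)
    high = cfg.stand_plateau_fraction * plateau
    m = round(cfg.sustained_s * fs)

    s2s_start = _first_sustained(total >= low, m)
    if s2s_start is None:
        raise SegmentationError("no sustained rise above the sit-to-stand onset level")
    s2s_end = _first_sustained(total >= high, m, start=s2s_start)
    if s2s_end is None:
        raise SegmentationError("standing plateau never reached")

    walk_starts = [s for s in swing_starts if s >= s2s_end]
    if not walk_starts:
        raise SegmentationError("no swing detected after sit-to-stand")
    walk_start = min(walk_starts)
    if last_onset <= walk_start:
        raise SegmentationError("walking window is degenerate")

    tug_end = _first_sustained(total < low, m, start=last_onset)
    if tug_end is None:
        raise SegmentationError("subject never returns to the seated baseline")

    steps = sum(1 for s in stance_onsets if walk_start <= s <= last_onset)
    return TUGSegmentation(
        sit_to_stand=(s2s_start / fs, s2s_end / fs),
        walking=(walk_start / fs, last_onset / fs),
        tug=(s2s_start / fs, tug_end / fs),
        step_count=steps,
    )


# ---------------------------------------------------------------------------
# stride length (ZUPT-corrected double integration)
# ---------------------------------------------------------------------------


def estimate_stride_lengths(accel_forward: np.ndarray, cycles: Sequence[GaitCycle],
                            fs: float) -> list[GaitCycle]:
    """Fill ``stride_length_m`` per cycle from the forward acceleration axis.

    Acceleration is integrated (trapezoidal) to velocity; velocity is
    pinned to zero at each cycle's stance midpoint (ZUPT anchors, linear
    detrend between consecutive anchors) and integrated again over the
    cycle.  Negative raw values are clamped to zero with
    ``stride_clamped`` set.
    """
    accel = np.asarray(accel_forward, dtype=float)
    if not cycles:
        return []
    if max(c.end_idx for c in cycles) > len(accel):
        raise DataValidationError("cycle extends beyond the acceleration series")
    dt = 1.0 / fs
    vel = np.concatenate(([0.0], np.cumsum((accel[1:] + accel[:-1]) / 2.0 * dt)))

    anchors = [c.start_idx + int(round(c.stance_s * fs / 2)) for c in cycles]
    anchors.append(cycles[-1].end_idx)  # heel strike: foot momentarily stationary
    anchors = np.array(sorted(set(min(a, len(accel) - 1) for a in anchors)))
    drift = np.interp(np.arange(len(accel)), anchors, vel[anchors])
    v_corr = vel - drift
    disp = np.concatenate(([0.0], np.cumsum((v_corr[1:] + v_corr[:-1]) / 2.0 * dt)))

    out = []
    last = len(accel) - 1
    for c in cycles:
        raw = float(disp[min(c.end_idx, last)] - disp[c.start_idx])
        if raw < 0:
            out.append(replace(c, stride_length_m=0.0, stride_clamped=True))
        else:
            out.append(replace(c, stride_length_m=raw, stride_clamped=False))
    return out
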