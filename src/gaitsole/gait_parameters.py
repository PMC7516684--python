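"""The spatiotemporal gait-parameter registry for one TUG trial.

A trial reduces to a fixed registry of 26 named parameters: the TUG
sub-phase times, cadence, walking speed and stride length, pooled
single/double-support statistics (seconds and as fractions of the mean
gait cycle), and per-side swing/stance statistics with their
sound-vs-hemiplegic asymmetry.  Twenty-two of these (all but the four
support-time percentage aggregates) form the correlation set used
against the clinical scales.

Percentage ("pct") fields are fractions of the mean gait cycle duration
(e.g. 0.15, not 15); the mean cycle duration is pooled over both feet of
the trial.  Asymmetry is the absolute difference of per-side means.  For
control subjects the hemiplegic/sound slots are filled by the
right/left side respectively (declared convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from typing import Optional, Sequence

import numpy as np

from .errors import DataValidationError, InputError
from .segmentation import GaitCycle, SupportInterval, TUGSegmentation

#: the full 26-name registry (trial row layout)
PARAMETER_REGISTRY = (
    "tug_time_s",
    "walking_time_s",
    "sit_to_stand_s",
    "cadence_steps_per_min",
    "walking_speed_m_per_s",
    "stride_length_m",
    "single_support_mean_s",
    "single_support_sd_s",
    "single_support_mean_pct",
    "single_support_sd_pct",
    "double_support_mean_s",
    "double_support_sd_s",
    "double_support_mean_pct",
    "double_support_sd_pct",
    "diff_swing_s",
    "diff_swing_pct",
    "diff_stance_s",
    "diff_stance_pct",
    "swing_hemi_mean_s",
    "swing_hemi_sd_s",
    "swing_sound_mean_s",
    "swing_sound_sd_s",
    "stance_hemi_mean_s",
    "stance_hemi_sd_s",
    "stance_sound_mean_s",
    "stance_sound_sd_s",
)

#: the 22 parameters entering the scale-correlation analysis
CORRELATION_PARAMETERS = tuple(
    name for name in PARAMETER_REGISTRY
    if name not in (
        "single_support_mean_pct", "single_support_sd_pct",
        "double_support_mean_pct", "double_support_sd_pct",
    )
)

_PCT_FIELDS = tuple(n for n in PARAMETER_REGISTRY if n.endswith("_pct"))


@dataclass
class GaitParameterSet:
    """One trial's values for the closed 26-name registry (NaN = missing)."""

    tug_time_s: float = math.nan
    walking_time_s: float = math.nan
    sit_to_stand_s: float = math.nan
    cadence_steps_per_min: float = math.nan
    walking_speed_m_per_s: float = math.nan
    stride_length_m: float = math.nan
    single_support_mean_s: float = math.nan
    single_support_sd_s: float = math.nan
    single_support_mean_pct: float = math.nan
    single_support_sd_pct: float = math.nan
    double_support_mean_s: float = math.nan
    double_support_sd_s: float = math.nan
    double_support_mean_pct: float = math.nan
    double_support_sd_pct: float = math.nan
    diff_swing_s: float = math.nan
    diff_swing_pct: float = math.nan
    diff_stance_s: float = math.nan
    diff_stance_pct: float = math.nan
    swing_hemi_mean_s: float = math.nan
    swing_hemi_sd_s: float = math.nan
    swing_sound_mean_s: float = math.nan
    swing_sound_sd_s: float = math.nan
    stance_hemi_mean_s: float = math.nan
    stance_hemi_sd_s: float = math.nan
    stance_sound_mean_s: float = math.nan
    stance_sound_sd_s: float = math.nan

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = float(getattr(self, f.name))
            setattr(self, f.name, v)
            if math.isnan(v):
                continue
            if v < 0:
                raise DataValidationError(f"{f.name} must be >= 0, got {v}")
            if f.name in _PCT_FIELDS and v > 1.5:
                raise DataValidationError(f"{f.name}={v} outside the sanity bound [0, 1.5]")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAMETER_REGISTRY}

    @classmethod
    def from_dict(cls, d: dict) -> "GaitParameterSet":
        return cls(**{name: d.get(name, math.nan) for name in PARAMETER_REGISTRY})


def _mean_sd(values: Sequence[float], ddof: int = 0) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return math.nan, math.nan
    if arr.size <= ddof:
        return float(arr.mean()), math.nan
    return float(arr.mean()), float(arr.std(ddof=ddof))


def hemi_sound_sides(affected_side: str) -> tuple[str, str]:
    """Map affected side to (hemi, sound); controls use (right, left)."""
    if affected_side == "left":
        return "left", "right"
    return "right", "left"


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def support_time_stats(support: Sequence[SupportInterval], mean_cycle_s: float,
                       fs: float, ddof: int = 0) -> dict[str, float]:
    """Pooled single/double support mean and SD, in seconds and cycle fractions.

    Single-support durations pool ``single_left`` and ``single_right``
    intervals; ``none`` intervals are excluded.  SDs are population SDs
    by default.  Empty categories yield NaN markers, not errors.
    """
    if not (mean_cycle_s > 0) and not math.isnan(mean_cycle_s):
        raise InputError("mean_cycle_s must be positive")
    single = [(s.end_idx - s.start_idx) / fs for s in support
              if s.kind in ("single_left", "single_right")]
    double = [(s.end_idx - s.start_idx) / fs for s in support if s.kind == "double"]
    sm, ssd = _mean_sd(single, ddof)
    dm, dsd = _mean_sd(double, ddof)
    return {
        "single_support_mean_s": sm,
        "single_support_sd_s": ssd,
        "single_support_mean_pct": sm / mean_cycle_s,
        "single_support_sd_pct": ssd / mean_cycle_s,
        "double_support_mean_s": dm,
        "double_support_sd_s": dsd,
        "double_support_mean_pct": dm / mean_cycle_s,
        "double_support_sd_pct": dsd / mean_cycle_s,
    }


def asymmetry_metrics(cycles_left: Sequence[GaitCycle], cycles_right: Sequence[GaitCycle],
                      affected_side: str, mean_cycle_s: float,
                      ddof: int = 0) -> dict[str, float]:
    """Per-side swing/stance statistics and sound-vs-hemiplegic differences.

    ``diff_*_s`` is the absolute difference of per-side mean durations;
    ``diff_*_pct`` divides that by the pooled mean gait cycle duration.
    Zero cycles on either foot yield NaN markers.
    """
    by_side = {"left": cycles_left, "right": cycles_right}
    hemi, sound = hemi_sound_sides(affected_side)
    out: dict[str, float] = {}
    stats = {}
    for slot, side in (("hemi", hemi), ("sound", sound)):
        cycles = by_side[side]
        sw_m, sw_sd = _mean_sd([c.swing_s for c in cycles], ddof)
        st_m, st_sd = _mean_sd([c.stance_s for c in cycles], ddof)
        out[f"swing_{slot}_mean_s"] = sw_m
        out[f"swing_{slot}_sd_s"] = sw_sd
        out[f"stance_{slot}_mean_s"] = st_m
        out[f"stance_{slot}_sd_s"] = st_sd
        stats[slot] = (sw_m, st_m)
    diff_swing = abs(stats["sound"][0] - stats["hemi"][0])
    diff_stance = abs(stats["sound"][1] - stats["hemi"][1])
    out["diff_swing_s"] = diff_swing
    out["diff_stance_s"] = diff_stance
    out["diff_swing_pct"] = diff_swing / mean_cycle_s
    out["diff_stance_pct"] = diff_stance / mean_cycle_s
    return out


def compute_parameter_set(tug_seg: Optional[TUGSegmentation],
                          cycles_left: Sequence[GaitCycle],
                          cycles_right: Sequence[GaitCycle],
                          support: Sequence[SupportInterval],
                          affected_side: str, fs: float, *,
                          speed_mode: str = "cycle",
                          track_length_m: Optional[float] = None,
                          ddof: int = 0) -> GaitParameterSet:
    """Assemble the full registry from one trial's segmentation outputs.

    Cycles and support intervals are expected to be restricted to the
    walking window.  ``speed_mode="cycle"`` uses the stride/cycle
    identity (walking speed = mean stride length / mean cycle duration);
    ``speed_mode="track"`` uses 2 x track length / walking time.
    """
    if tug_seg is None:
        raise InputError("TUG segmentation missing: trial unusable")
    all_cycles = list(cycles_left) + list(cycles_right)
    mean_cycle = (
        float(np.mean([c.cycle_s for c in all_cycles])) if all_cycles else math.nan
    )
    strides = [c.stride_length_m for c in all_cycles if c.stride_length_m is not None]
    stride_mean = float(np.mean(strides)) if strides else math.nan

    if speed_mode == "track":
        if track_length_m is None:
            raise InputError("speed_mode='track' requires track_length_m")
        speed = 2.0 * track_length_m / tug_seg.walking_time_s
    elif speed_mode == "cycle":
        speed = stride_mean / mean_cycle
    else:
        raise InputError(f"unknown speed_mode {speed_mode!r}")

    values: dict[str, float] = {
        "tug_time_s": tug_seg.tug_time_s,
        "walking_time_s": tug_seg.walking_time_s,
        "sit_to_stand_s": tug_seg.sit_to_stand_s,
        "cadence_steps_per_min": tug_seg.step_count / tug_seg.walking_time_s * 60.0,
        "walking_speed_m_per_s": speed,
        "stride_length_m": stride_mean,
    }
    values.update(support_time_stats(support, mean_cycle, fs, ddof=ddof))
    values.update(asymmetry_metrics(cycles_left, cycles_right, affected_side,
                                    mean_cycle, ddof=ddof))
    return GaitParameterSet.from_dict(values)


# ---------------------------------------------------------------------------
# walking-window helpers
# ---------------------------------------------------------------------------


def cycles_in_window(cycles: Sequence[GaitCycle], start_s: float, end_s: float,
                     fs: float) -> list[GaitCycle]:
    """Keep cycles fully contained in [start_s, end_s] (sample tolerance 1)."""
    lo = start_s * fs - 1.0
    hi = end_s * fs + 1.0
    return [c for c in cycles if c.start_idx >= lo and c.end_idx <= hi]


def clip_support(support: Sequence[SupportInterval], start_idx: int,
                 end_idx: int) -> list[SupportInterval]:
    """Clip support intervals to a sample window, dropping empty remainders."""
    out = []
    for s in support:
        a, b = max(s.start_idx, start_idx), min(s.end_idx, end_idx)
        if b > a:
            out.append(SupportInterval(s.kind, a, b))
    return out
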