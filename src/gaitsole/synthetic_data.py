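"""Synthetic TUG trial and cohort generator with exact ground truth.

Generates bilateral insole recordings for a Timed Up and Go trial
(sit -> sit-to-stand -> walk -> turn -> walk back -> sit down) whose
swing/stance timing, double-support overlaps, stride lengths and TUG
sub-phase windows are known in closed form, so the full segmentation and
parameter pipeline can be validated without patient data.

Timing model
------------
Walking is an alternating step sequence with a fixed double-support
overlap ``d`` at every step transition: a foot lands ``d`` seconds
before the contralateral foot lifts.  In steady gait this couples the
per-side durations through the identity

    stance(side) = swing(contralateral side) + 2 d

so one of (stance, swing) per side is free and the other is derived.
:class:`GaitConfig` accepts either and checks consistency when both are
given.  Per-step swing durations are truncated-normal draws (floor
0.1 s); hemiplegic gait is emulated by a longer hemiplegic-side swing,
which by the identity above produces the longer *sound*-side stance
seen in stroke gait.

Pressure model
--------------
During each walking stance the load rolls heel -> toe over three channel
zones (p1-p2, p3-p5, p6-p8), each active zone at ``pressure_peak_Ncm2``;
swing frames carry folded-normal sensor noise whose tail probability of
crossing the 4.3 N/cm^2 activation threshold is negligible (< 1e-6 per
channel-frame at the default SD).  Sit-to-stand is a monotone bilateral
ramp whose endpoints coincide with the true window landmarks: weight
jumps to ~60% of the standing load when rising begins and settles with a
small terminal step; seat contact unloads the feet abruptly.

The forward-axis acceleration is the derivative of a sin^4 swing
velocity bell whose integral equals the cycle's true stride length;
velocity, acceleration and jerk all vanish at the swing boundaries, so
discrete re-integration is well conditioned.  The foot frame is
gravity-compensated by convention, so no orientation filtering is
modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigError, DataValidationError
from .gait_parameters import GaitParameterSet, hemi_sound_sides
from .sensor_model import ClinicalScores, InsoleRecording, SubjectRecord, TrialMeta, TrialRecording

#: activation threshold the generator's noise/tail guarantees are stated against
ACTIVATION_THRESHOLD_NCM2 = 4.3

#: duration floor for truncated-normal step draws (s)
DURATION_FLOOR_S = 0.1

# pressure ramp shape (fractions of the standing load): rising starts at
# UP_R0, grows linearly to UP_R1, steps to 1.0 when standing is reached;
# sitting down descends linearly to DOWN_R1 and drops to zero at seat
# contact.  DOWN_R1 keeps every loaded channel clearly above the activation
# threshold until seat contact, so unloading cannot chatter around it.
UP_R0, UP_R1, DOWN_R1 = 0.6, 0.89, 0.55

#: per-foot standing load distribution over the 8 channels, x pressure_peak
STANDING_WEIGHTS = np.array([0.5, 0.5, 0.25, 0.25, 0.25, 0.25, 0.25, 0.25])

_ZONES = (slice(0, 2), slice(2, 5), slice(5, 8))  # heel, midfoot, forefoot


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  floor: float, size: Optional[int] = None):
    draw = rng.normal(mean, sd, size=size) if sd > 0 else (
        np.full(size, mean) if size is not None else mean
    )
    return np.maximum(draw, floor) if size is not None else max(draw, floor)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class GaitConfig:
    """Timing, spatial and noise parameters of one simulated TUG trial.

    Per-side timing may be given as stance or swing means/SDs (seconds);
    the other is derived from the double-support identity.  Segment
    durations (``sit_s`` ...) are seconds; the turn is modelled as
    ``turn_s`` of continued stepping appended to ``n_strides_per_leg``.
    """

    # per-side timing: give swing_* or stance_* (or consistent both)
    swing_mean_left_s: Optional[float] = None
    swing_sd_left_s: Optional[float] = None
    swing_mean_right_s: Optional[float] = None
    swing_sd_right_s: Optional[float] = None
    stance_mean_left_s: Optional[float] = None
    stance_sd_left_s: Optional[float] = None
    stance_mean_right_s: Optional[float] = None
    stance_sd_right_s: Optional[float] = None
    double_support_target_s: float = 0.12
    stride_length_mean_m: float = 0.9
    stride_length_sd_m: float = 0.02
    n_strides_per_leg: int = 6
    sit_s: float = 2.0
    sit_to_stand_s: float = 2.9
    turn_s: float = 1.0
    stand_to_sit_s: float = 2.0
    stand_pause_s: float = 0.35
    trailing_sit_s: float = 0.4
    pressure_peak_Ncm2: float = 20.0
    pressure_noise_sd_Ncm2: float = 0.5
    accel_noise_sd: float = 0.05
    gyro_noise_sd: float = 1.0
    fs: float = 100.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        d = self.double_support_target_s
        if not (d > 0):
            raise ConfigError("double_support_target_s must be positive")

        def resolve(swing_m, swing_sd, stance_m, stance_sd, side):
            # identity: stance(other) = swing(side) + 2 d
            if swing_m is None and stance_m is None:
                raise ConfigError(f"no timing given for the {side} swing")
            if swing_m is None:
                swing_m = stance_m - 2 * d
            elif stance_m is not None and abs(stance_m - (swing_m + 2 * d)) > 1e-9:
                raise ConfigError(
                    f"inconsistent timing: stance {stance_m} != swing {swing_m} + 2*{d}"
                )
            if swing_sd is None:
                swing_sd = stance_sd if stance_sd is not None else 0.0
            elif stance_sd is not None and abs(stance_sd - swing_sd) > 1e-9:
                raise ConfigError("stance and swing SDs must match (stance = swing + 2d)")
            return swing_m, swing_sd

        # left swing is tied to right stance and vice versa
        self.swing_mean_left_s, self.swing_sd_left_s = resolve(
            self.swing_mean_left_s, self.swing_sd_left_s,
            self.stance_mean_right_s, self.stance_sd_right_s, "left")
        self.swing_mean_right_s, self.swing_sd_right_s = resolve(
            self.swing_mean_right_s, self.swing_sd_right_s,
            self.stance_mean_left_s, self.stance_sd_left_s, "right")
        self.stance_mean_right_s = self.swing_mean_left_s + 2 * d
        self.stance_sd_right_s = self.swing_sd_left_s
        self.stance_mean_left_s = self.swing_mean_right_s + 2 * d
        self.stance_sd_left_s = self.swing_sd_right_s

        for side in ("left", "right"):
            sw = getattr(self, f"swing_mean_{side}_s")
            st = getattr(self, f"stance_mean_{side}_s")
            if sw < DURATION_FLOOR_S:
                raise ConfigError(
                    f"double_support_target_s={d} too large for the configured "
                    f"stance/swing timing: {side} swing mean {sw:.3f}s falls below "
                    f"the {DURATION_FLOOR_S}s floor (single support would vanish)"
                )
            if getattr(self, f"swing_sd_{side}_s") < 0:
                raise ConfigError("swing SDs must be >= 0")

        for name in ("stride_length_mean_m", "sit_s", "sit_to_stand_s",
                     "stand_to_sit_s", "stand_pause_s", "trailing_sit_s", "fs"):
            if not (getattr(self, name) > 0):
                raise ConfigError(f"{name} must be positive")
        if self.turn_s < 0 or self.stride_length_sd_m < 0:
            raise ConfigError("turn_s and stride_length_sd_m must be >= 0")
        if self.n_strides_per_leg < 1:
            raise ConfigError("n_strides_per_leg must be >= 1")
        if not (self.pressure_peak_Ncm2 > ACTIVATION_THRESHOLD_NCM2):
            raise ConfigError(
                f"pressure_peak_Ncm2 must exceed the activation threshold "
                f"{ACTIVATION_THRESHOLD_NCM2}"
            )
        if self.pressure_noise_sd_Ncm2 < 0 or self.accel_noise_sd < 0 or self.gyro_noise_sd < 0:
            raise ConfigError("noise SDs must be >= 0")
        if self.pressure_noise_sd_Ncm2 > ACTIVATION_THRESHOLD_NCM2 / 4.9:
            # folded-normal tail: P(|N(0,sd)| >= 4.3) < 1e-6 requires sd <~ 0.88
            raise ConfigError(
                "pressure_noise_sd_Ncm2 too large: swing frames could cross the "
                "activation threshold with non-negligible probability"
            )
        if self.sit_s < 1.0:
            raise ConfigError("sit_s must be >= 1 s (seated baseline window)")

    # -- derived quantities ------------------------------------------------

    @property
    def cycle_mean_s(self) -> float:
        """Nominal gait cycle duration (identical for both feet)."""
        return self.swing_mean_left_s + self.swing_mean_right_s + 2 * self.double_support_target_s

    @property
    def n_strides_total(self) -> int:
        """Strides per leg including the turn's continued stepping."""
        return self.n_strides_per_leg + int(round(self.turn_s / self.cycle_mean_s))

    # -- factories ---------------------------------------------------------

    @classmethod
    def symmetric(cls, swing_mean_s: float, swing_sd_s: float = 0.0,
                  double_support_s: float = 0.12, **kw) -> "GaitConfig":
        return cls(
            swing_mean_left_s=swing_mean_s, swing_sd_left_s=swing_sd_s,
            swing_mean_right_s=swing_mean_s, swing_sd_right_s=swing_sd_s,
            double_support_target_s=double_support_s, **kw)

    @classmethod
    def asymmetric(cls, swing_sound_s: float, swing_hemi_s: float,
                   affected_side: str, swing_sound_sd_s: float = 0.0,
                   swing_hemi_sd_s: float = 0.0,
                   double_support_s: float = 0.12, **kw) -> "GaitConfig":
        hemi, sound = hemi_sound_sides(affected_side)
        vals = {
            f"swing_mean_{hemi}_s": swing_hemi_s,
            f"swing_sd_{hemi}_s": swing_hemi_sd_s,
            f"swing_mean_{sound}_s": swing_sound_s,
            f"swing_sd_{sound}_s": swing_sound_sd_s,
        }
        return cls(double_support_target_s=double_support_s, **vals, **kw)


def default_control_config(**kw) -> GaitConfig:
    """Healthy-adult TUG defaults (cycle ~1.04 s, speed ~0.88 m/s)."""
    kw.setdefault("stride_length_mean_m", 0.91)
    kw.setdefault("stride_length_sd_m", 0.02)
    kw.setdefault("n_strides_per_leg", 6)
    kw.setdefault("sit_to_stand_s", 2.9)
    kw.setdefault("turn_s", 1.0)
    return GaitConfig.symmetric(swing_mean_s=0.40, swing_sd_s=0.015,
                                double_support_s=0.12, **kw)


def default_patient_config(affected_side: str = "right", **kw) -> GaitConfig:
    """Chronic hemiplegic TUG defaults (cycle ~1.32 s, speed ~0.30 m/s,
    sound-minus-hemiplegic stance difference 0.27 s)."""
    kw.setdefault("stride_length_mean_m", 0.40)
    kw.setdefault("stride_length_sd_m", 0.03)
    kw.setdefault("n_strides_per_leg", 14)
    kw.setdefault("sit_to_stand_s", 4.0)
    kw.setdefault("turn_s", 2.0)
    kw.setdefault("stand_to_sit_s", 2.5)
    return GaitConfig.asymmetric(
        swing_sound_s=0.335, swing_hemi_s=0.605, affected_side=affected_side,
        swing_sound_sd_s=0.03, swing_hemi_sd_s=0.05, double_support_s=0.19, **kw)


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------


@dataclass
class TruthCycle:
    """True stance-onset-to-stance-onset cycle of one foot (seconds)."""

    start_s: float
    end_s: float
    stance_s: float
    swing_s: float
    cycle_s: float
    stride_m: float


@dataclass
class GroundTruth:
    """Exact event times and windows underlying one simulated trial."""

    fs: float
    stance_intervals: dict  # side -> list[(start_s, end_s)]
    onsets: dict  # side -> walking stance-onset times
    toeoffs: dict  # side -> walking toe-off times
    cycles: dict  # side -> list[TruthCycle]
    sit_to_stand: tuple[float, float]
    walking: tuple[float, float]
    tug: tuple[float, float]
    step_count: int
    duration_s: float

    def __post_init__(self) -> None:
        for side, ivals in self.stance_intervals.items():
            prev_end = -math.inf
            for a, b in ivals:
                if not (a < b) or a < prev_end:
                    raise DataValidationError(
                        f"{side} truth stance intervals not increasing/disjoint"
                    )
                prev_end = b
        for side, cyc in self.cycles.items():
            for c in cyc:
                if abs(c.stance_s + c.swing_s - c.cycle_s) > 1e-9:
                    raise DataValidationError("truth cycle durations inconsistent")
                if abs((c.end_s - c.start_s) - c.cycle_s) > 1e-9:
                    raise DataValidationError("truth cycle endpoints inconsistent")

    def transitions(self, side: str) -> np.ndarray:
        """Walking-window phase transition times (toe-offs and onsets)."""
        return np.sort(np.concatenate([self.onsets[side], self.toeoffs[side]]))


# ---------------------------------------------------------------------------
# timeline construction
# ---------------------------------------------------------------------------


def build_gait_timeline(config: GaitConfig, rng: np.random.Generator):
    """Alternating stance/swing event times for both feet plus GroundTruth.

    Returns ``(left_stance_intervals, right_stance_intervals, truth)``
    with intervals in seconds.  Per-step swing durations are
    truncated-normal draws; every step transition overlaps by exactly
    ``double_support_target_s``, so no both-feet-swing instant exists in
    the walking window.
    """
    d = config.double_support_target_s
    ramp_start = config.sit_s
    ramp_end = ramp_start + config.sit_to_stand_s
    walk_t0 = ramp_end + config.stand_pause_s
    n_total = config.n_strides_total

    swings = {"left": [], "right": []}
    strides = {"left": [], "right": []}
    onsets = {"left": [], "right": []}
    toeoffs = {"left": [], "right": []}
    intervals = {"left": [], "right": []}
    stance_start = {"left": ramp_start, "right": ramp_start}
    done = {"left": 0, "right": 0}

    side, other = "right", "left"
    t_off = walk_t0
    while done[side] < n_total:
        sw = _trunc_normal(rng, getattr(config, f"swing_mean_{side}_s"),
                           getattr(config, f"swing_sd_{side}_s"), DURATION_FLOOR_S)
        stride = _trunc_normal(rng, config.stride_length_mean_m,
                               config.stride_length_sd_m, 0.05)
        intervals[side].append((stance_start[side], t_off))
        toeoffs[side].append(t_off)
        land = t_off + sw
        onsets[side].append(land)
        swings[side].append(sw)
        strides[side].append(stride)
        stance_start[side] = land
        done[side] += 1
        if done[other] < n_total:
            t_off = land + d
            side, other = other, side
        else:
            break

    t_last = max(onsets["left"][-1], onsets["right"][-1])
    down_start = t_last + config.stand_pause_s
    seat_contact = down_start + config.stand_to_sit_s
    duration = seat_contact + config.trailing_sit_s

    # terminal stance ends when the heel channel drops below the activation
    # threshold on the descending ramp (or at seat contact if it never does)
    heel_level = STANDING_WEIGHTS[0] * config.pressure_peak_Ncm2
    frac = ACTIVATION_THRESHOLD_NCM2 / heel_level
    if frac <= DOWN_R1:
        deact = seat_contact
    else:
        deact = down_start + (1.0 - frac) / (1.0 - DOWN_R1) * config.stand_to_sit_s
    for side_ in ("left", "right"):
        intervals[side_].append((stance_start[side_], deact))

    cycles = {}
    for side_ in ("left", "right"):
        cyc = []
        for k in range(n_total - 1):
            start = onsets[side_][k]
            end = onsets[side_][k + 1]
            stance = toeoffs[side_][k + 1] - start
            swing = swings[side_][k + 1]
            cyc.append(TruthCycle(start_s=start, end_s=end, stance_s=stance,
                                  swing_s=swing, cycle_s=end - start,
                                  stride_m=strides[side_][k + 1]))
        cycles[side_] = cyc

    truth = GroundTruth(
        fs=config.fs,
        stance_intervals={s: list(intervals[s]) for s in ("left", "right")},
        onsets={s: np.array(onsets[s]) for s in ("left", "right")},
        toeoffs={s: np.array(toeoffs[s]) for s in ("left", "right")},
        cycles=cycles,
        sit_to_stand=(ramp_start, ramp_end),
        walking=(walk_t0, t_last),
        tug=(ramp_start, seat_contact),
        step_count=2 * n_total,
        duration_s=duration,
    )
    # swing draws are carried for signal synthesis
    truth._swings = swings  # type: ignore[attr-defined]
    truth._strides = strides  # type: ignore[attr-defined]
    truth._landmarks = {  # type: ignore[attr-defined]
        "ramp_start": ramp_start, "ramp_end": ramp_end,
        "down_start": down_start, "seat_contact": seat_contact,
    }
    return intervals["left"], intervals["right"], truth


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------


def _frame_range(start_s: float, end_s: float, fs: float, n: int) -> tuple[int, int]:
    a = int(math.ceil(start_s * fs - 1e-9))
    b = int(math.ceil(end_s * fs - 1e-9))
    return max(a, 0), min(b, n)


def synthesize_signals(truth: GroundTruth, config: GaitConfig,
                       rng: np.random.Generator,
                       meta: Optional[TrialMeta] = None) -> TrialRecording:
    """Rasterize a timeline into a noisy bilateral :class:`TrialRecording`."""
    fs = config.fs
    n = int(round(truth.duration_s * fs))
    lm = truth._landmarks  # type: ignore[attr-defined]
    peak = config.pressure_peak_Ncm2
    standing = STANDING_WEIGHTS * peak
    t_grid = np.arange(n) / fs

    recordings = {}
    for side in ("left", "right"):
        clean = np.zeros((n, 8))
        for (a_s, b_s) in truth.stance_intervals[side]:
            ia, ib = _frame_range(a_s, b_s, fs, n)
            if ib <= ia:
                continue
            if a_s <= lm["ramp_start"] + 1e-12:
                # initial stance: rising ramp then full standing load
                ra, rb = _frame_range(lm["ramp_start"], lm["ramp_end"], fs, n)
                u = (t_grid[ra:rb] - lm["ramp_start"]) / config.sit_to_stand_s
                r = UP_R0 + (UP_R1 - UP_R0) * u
                clean[ra:rb] = standing[None, :] * r[:, None]
                clean[rb:ib] = standing[None, :]
            elif b_s >= lm["down_start"] - 1e-12:
                # terminal stance: standing load then descending ramp
                da, db = _frame_range(lm["down_start"], lm["seat_contact"], fs, n)
                clean[ia:da] = standing[None, :]
                u = (t_grid[da:db] - lm["down_start"]) / config.stand_to_sit_s
                r = 1.0 + (DOWN_R1 - 1.0) * u
                clean[da:db] = standing[None, :] * r[:, None]
            else:
                # walking stance: heel -> midfoot -> forefoot rollover
                third = (b_s - a_s) / 3.0
                for z, zone in enumerate(_ZONES):
                    za, zb = _frame_range(a_s + z * third, a_s + (z + 1) * third, fs, n)
                    clean[za:zb, zone] = peak

        noise = rng.normal(0.0, config.pressure_noise_sd_Ncm2, size=(n, 8)) \
            if config.pressure_noise_sd_Ncm2 > 0 else np.zeros((n, 8))
        pressure = np.where(clean > 0, np.maximum(clean + noise, 0.0), np.abs(noise))

        accel = rng.normal(0.0, config.accel_noise_sd, size=(n, 3)) \
            if config.accel_noise_sd > 0 else np.zeros((n, 3))
        for t_off, land, stride in zip(
            truth.toeoffs[side], truth.onsets[side],
            truth._strides[side],  # type: ignore[attr-defined]
        ):
            # sin^4 velocity bell: velocity, acceleration and jerk all vanish
            # at the swing boundaries (well-conditioned discrete integration);
            # the integral of v over the swing equals the stride length exactly
            ts = land - t_off
            vmax = 8.0 * stride / (3.0 * ts)
            ia, ib = _frame_range(t_off, land, fs, n)
            tau = math.pi * (t_grid[ia:ib] - t_off) / ts
            accel[ia:ib, 0] += 4.0 * vmax * math.pi / ts * np.sin(tau) ** 3 * np.cos(tau)

        gyro = rng.normal(0.0, config.gyro_noise_sd, size=(n, 3)) \
            if config.gyro_noise_sd > 0 else np.zeros((n, 3))

        recordings[side] = InsoleRecording(side=side, fs=fs, pressure=pressure,
                                           accel=accel, gyro=gyro)

    if meta is None:
        meta = TrialMeta(subject_id="sim", group="control", affected_side="none")
    return TrialRecording(left=recordings["left"], right=recordings["right"], meta=meta)


def simulate_tug_trial(config: GaitConfig, seed: Optional[int] = None,
                       meta: Optional[TrialMeta] = None
                       ) -> tuple[TrialRecording, GroundTruth]:
    """Generate one complete TUG trial; identical seeds give identical output."""
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    _, _, truth = build_gait_timeline(config, rng)
    trial = synthesize_signals(truth, config, rng, meta=meta)
    return trial, truth


# ---------------------------------------------------------------------------
# truth-derived parameters
# ---------------------------------------------------------------------------


def _truth_support_durations(truth: GroundTruth) -> tuple[list[float], list[float]]:
    """Single/double support durations inside the true walking window."""
    w0, w1 = truth.walking

    def clipped(side):
        out = []
        for a, b in truth.stance_intervals[side]:
            a2, b2 = max(a, w0), min(b, w1)
            if b2 > a2:
                out.append((a2, b2))
        return out

    left, right = clipped("left"), clipped("right")
    bounds = sorted({w0, w1, *(x for iv in left + right for x in iv)})

    def inside(ivals, t):
        return any(a <= t < b for a, b in ivals)

    segs = []  # (kind, duration)
    for a, b in zip(bounds[:-1], bounds[1:]):
        mid = (a + b) / 2.0
        l_in, r_in = inside(left, mid), inside(right, mid)
        kind = "double" if (l_in and r_in) else (
            "single" if (l_in or r_in) else "none")
        if segs and segs[-1][0] == kind:
            segs[-1] = (kind, segs[-1][1] + (b - a))
        else:
            segs.append((kind, b - a))
    single = [dur for k, dur in segs if k == "single"]
    double = [dur for k, dur in segs if k == "double"]
    return single, double


def truth_parameter_set(truth: GroundTruth, affected_side: str = "none"
                        ) -> GaitParameterSet:
    """The registry evaluated analytically from the generating event times."""
    cycles_all = truth.cycles["left"] + truth.cycles["right"]
    mean_cycle = float(np.mean([c.cycle_s for c in cycles_all]))
    stride = float(np.mean([c.stride_m for c in cycles_all]))
    single, double = _truth_support_durations(truth)
    hemi, sound = hemi_sound_sides(affected_side)

    def stats(vals):
        arr = np.asarray(vals, dtype=float)
        return (float(arr.mean()), float(arr.std())) if arr.size else (math.nan, math.nan)

    out = {
        "tug_time_s": truth.tug[1] - truth.tug[0],
        "walking_time_s": truth.walking[1] - truth.walking[0],
        "sit_to_stand_s": truth.sit_to_stand[1] - truth.sit_to_stand[0],
        "cadence_steps_per_min": truth.step_count / (truth.walking[1] - truth.walking[0]) * 60.0,
        "walking_speed_m_per_s": stride / mean_cycle,
        "stride_length_m": stride,
    }
    sm, ssd = stats(single)
    dm, dsd = stats(double)
    out.update({
        "single_support_mean_s": sm, "single_support_sd_s": ssd,
        "single_support_mean_pct": sm / mean_cycle, "single_support_sd_pct": ssd / mean_cycle,
        "double_support_mean_s": dm, "double_support_sd_s": dsd,
        "double_support_mean_pct": dm / mean_cycle, "double_support_sd_pct": dsd / mean_cycle,
    })
    side_stats = {}
    for slot, side in (("hemi", hemi), ("sound", sound)):
        sw_m, sw_sd = stats([c.swing_s for c in truth.cycles[side]])
        st_m, st_sd = stats([c.stance_s for c in truth.cycles[side]])
        out[f"swing_{slot}_mean_s"], out[f"swing_{slot}_sd_s"] = sw_m, sw_sd
        out[f"stance_{slot}_mean_s"], out[f"stance_{slot}_sd_s"] = st_m, st_sd
        side_stats[slot] = (sw_m, st_m)
    out["diff_swing_s"] = abs(side_stats["sound"][0] - side_stats["hemi"][0])
    out["diff_stance_s"] = abs(side_stats["sound"][1] - side_stats["hemi"][1])
    out["diff_swing_pct"] = out["diff_swing_s"] / mean_cycle
    out["diff_stance_pct"] = out["diff_stance_s"] / mean_cycle
    return GaitParameterSet.from_dict(out)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass
class ScoreModel:
    """Linear-plus-noise clinical score model: score = a + b * diff_stance_pct + e."""

    a: float
    b: float
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ConfigError("score model sigma must be >= 0")


@dataclass
class CohortConfig:
    """A synthetic study cohort: asymmetric patients vs symmetric controls.

    Per-subject gait means are drawn around the base configs with the
    ``*_between_sd`` spreads; clinical scores for scales with a
    :class:`ScoreModel` are generated from each subject's *true*
    ``diff_stance_pct`` (b < 0 in the default model: worse asymmetry,
    lower FMA lower-extremity score).  Scales without a model are drawn
    from independent clinical-range distributions.
    """

    n_patients: int = 10
    n_controls: int = 10
    patient_base: GaitConfig = field(default_factory=default_patient_config)
    control_base: GaitConfig = field(default_factory=default_control_config)
    patient_swing_sound_between_sd: float = 0.04
    patient_swing_hemi_between_sd: float = 0.09
    patient_stride_between_sd: float = 0.07
    patient_ds_between_sd: float = 0.02
    patient_s2s_between_sd: float = 1.0
    control_swing_between_sd: float = 0.02
    control_stride_between_sd: float = 0.04
    control_ds_between_sd: float = 0.01
    control_s2s_between_sd: float = 0.3
    track_length_m: float = 3.0
    score_models: dict = field(default_factory=lambda: {
        "fma_lex": ScoreModel(a=26.39, b=-38.64, sigma=2.35),
    })
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_patients < 2 or self.n_controls < 2:
            raise ConfigError("need >= 2 subjects per group for downstream statistics")
        for name, model in self.score_models.items():
            if name not in ("fma_lex", "fma_uex", "mmse", "mbi"):
                raise ConfigError(f"unknown scale {name!r} in score_models")
            if not isinstance(model, ScoreModel):
                raise ConfigError("score_models values must be ScoreModel instances")


# independent clinical-range draws for scales without a generating model
# (location/scale echo a chronic-stroke cohort; clipped to instrument ranges)
_BASELINE_SCORES = {
    "mmse": (24.4, 4.9, 0.0, 30.0),
    "mbi": (59.0, 20.0, 0.0, 100.0),
    "fma_uex": (25.5, 12.0, 0.0, 66.0),
    "fma_lex": (19.0, 6.0, 0.0, 34.0),
}


def _draw_patient_config(cfg: CohortConfig, base: GaitConfig,
                         rng: np.random.Generator, affected_side: str) -> GaitConfig:
    # convention: patient_base carries the hemiplegic timing on its right side
    base_hemi = cfg.patient_base.swing_mean_right_s
    base_sound = cfg.patient_base.swing_mean_left_s
    sound_m = _trunc_normal(rng, base_sound, cfg.patient_swing_sound_between_sd, 0.15)
    hemi_m = _trunc_normal(rng, base_hemi, cfg.patient_swing_hemi_between_sd, 0.15)
    hemi_m = max(hemi_m, sound_m + 0.01)  # hemiplegic swing exceeds sound swing
    ds = _trunc_normal(rng, base.double_support_target_s, cfg.patient_ds_between_sd, 0.06)
    stride = _trunc_normal(rng, base.stride_length_mean_m, cfg.patient_stride_between_sd, 0.12)
    s2s = _trunc_normal(rng, base.sit_to_stand_s, cfg.patient_s2s_between_sd, 1.2)
    n_strides = int(np.clip(round(2.0 * cfg.track_length_m / stride), 4, 40))
    return GaitConfig.asymmetric(
        swing_sound_s=sound_m, swing_hemi_s=hemi_m, affected_side=affected_side,
        swing_sound_sd_s=base.swing_sd_left_s, swing_hemi_sd_s=base.swing_sd_right_s,
        double_support_s=ds, stride_length_mean_m=stride,
        stride_length_sd_m=base.stride_length_sd_m, n_strides_per_leg=n_strides,
        sit_s=base.sit_s, sit_to_stand_s=s2s, turn_s=base.turn_s,
        stand_to_sit_s=base.stand_to_sit_s, stand_pause_s=base.stand_pause_s,
        trailing_sit_s=base.trailing_sit_s,
        pressure_peak_Ncm2=base.pressure_peak_Ncm2,
        pressure_noise_sd_Ncm2=base.pressure_noise_sd_Ncm2,
        accel_noise_sd=base.accel_noise_sd, fs=base.fs)


def _draw_control_config(cfg: CohortConfig, base: GaitConfig,
                         rng: np.random.Generator) -> GaitConfig:
    swing = _trunc_normal(rng, base.swing_mean_left_s, cfg.control_swing_between_sd, 0.15)
    ds = _trunc_normal(rng, base.double_support_target_s, cfg.control_ds_between_sd, 0.05)
    stride = _trunc_normal(rng, base.stride_length_mean_m, cfg.control_stride_between_sd, 0.3)
    s2s = _trunc_normal(rng, base.sit_to_stand_s, cfg.control_s2s_between_sd, 1.2)
    n_strides = int(np.clip(round(2.0 * cfg.track_length_m / stride), 4, 40))
    return GaitConfig.symmetric(
        swing_mean_s=swing, swing_sd_s=base.swing_sd_left_s, double_support_s=ds,
        stride_length_mean_m=stride, stride_length_sd_m=base.stride_length_sd_m,
        n_strides_per_leg=n_strides, sit_s=base.sit_s, sit_to_stand_s=s2s,
        turn_s=base.turn_s, stand_to_sit_s=base.stand_to_sit_s,
        stand_pause_s=base.stand_pause_s, trailing_sit_s=base.trailing_sit_s,
        pressure_peak_Ncm2=base.pressure_peak_Ncm2,
        pressure_noise_sd_Ncm2=base.pressure_noise_sd_Ncm2,
        accel_noise_sd=base.accel_noise_sd, fs=base.fs)


def simulate_cohort(config: CohortConfig, seed: Optional[int] = None):
    """Simulate a full study cohort with per-subject ground truth.

    Returns ``(trials, records, truths)``: the bilateral recordings, one
    :class:`SubjectRecord` per subject carrying the *true* parameter set
    and generated clinical scores, and the per-subject
    :class:`GroundTruth` objects.  Reproducible by seed.
    """
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    master = np.random.default_rng(ss)

    subjects = [("patient", f"P{i + 1:02d}") for i in range(config.n_patients)]
    subjects += [("control", f"C{i + 1:02d}") for i in range(config.n_controls)]
    children = ss.spawn(len(subjects))

    trials, records, truths = [], [], []
    for (group, sid), child in zip(subjects, children):
        rng = np.random.default_rng(child)
        if group == "patient":
            affected = "left" if rng.random() < 0.5 else "right"
            gc = _draw_patient_config(config, config.patient_base, rng, affected)
        else:
            affected = "none"
            gc = _draw_control_config(config, config.control_base, rng)
        meta = TrialMeta(subject_id=sid, group=group, affected_side=affected,
                         track_length_m=config.track_length_m)
        _, _, truth = build_gait_timeline(gc, rng)
        trial = synthesize_signals(truth, gc, rng, meta=meta)
        true_params = truth_parameter_set(truth, affected)

        scores = None
        if group == "patient":
            vals = {}
            for scale, (mu, sd, lo, hi) in _BASELINE_SCORES.items():
                model = config.score_models.get(scale)
                if model is not None:
                    v = model.a + model.b * true_params.diff_stance_pct
                    if model.sigma > 0:
                        v += rng.normal(0.0, model.sigma)
                else:
                    v = float(np.clip(rng.normal(mu, sd), lo, hi))
                vals[scale] = max(v, 0.0) if scale.startswith("fma") else v
            scores = ClinicalScores(**vals)

        trials.append(trial)
        records.append(SubjectRecord(subject_id=sid, group=group,
                                     affected_side=affected, scores=scores,
                                     params=true_params))
        truths.append(truth)
    return trials, records, truths


def sigma_for_target_r2(config: CohortConfig, b: float, target_r2: float) -> float:
    """Noise SD giving an expected generating R^2 for the fma_lex model.

    Uses the analytic between-subject SD of the true stance-difference
    fraction implied by the cohort config.
    """
    if not (0 < target_r2 < 1):
        raise ConfigError("target_r2 must lie in (0, 1)")
    var_diff = (config.patient_swing_sound_between_sd ** 2
                + config.patient_swing_hemi_between_sd ** 2)
    cycle = config.patient_base.cycle_mean_s
    var_x = var_diff / cycle ** 2
    return math.sqrt(b * b * var_x * (1.0 - target_r2) / target_r2)
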