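"""End-to-end orchestration: simulate -> extract -> analyze.

Library-level entry points behind the ``gaitsole`` command line:
:func:`run_simulate` writes a synthetic cohort to disk in the standard
trial layout, :func:`run_extract` turns trials into a ``parameters.csv``
row per subject (with per-trial QC), and :func:`run_analyze` produces
the group-comparison, scale-correlation and outlier-refit tables.
Every output file carries a provenance header (tool version, config
hash, seed), and the whole chain is deterministic given (config, seed).

Failed trials degrade to missing rows rather than aborting the cohort.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import os
import time
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, GaitsoleError, SegmentationError
from .gait_parameters import (
    GaitParameterSet,
    PARAMETER_REGISTRY,
    clip_support,
    compute_parameter_set,
    cycles_in_window,
)
from .sensor_model import (
    ClinicalScores,
    SubjectRecord,
    TrialRecording,
    load_trial_dir,
    read_manifest,
    write_manifest,
    write_trial,
)
from .segmentation import (
    SegmentationConfig,
    classify_support,
    detect_phases,
    estimate_stride_lengths,
    extract_cycles,
    preprocess_and_count,
    segment_tug,
)
from .synthetic_data import (
    CohortConfig,
    GaitConfig,
    GroundTruth,
    ScoreModel,
    simulate_cohort,
    simulate_tug_trial,
)
from .cohort_stats import compare_groups, correlate_scales, refit_without_outlier

log = logging.getLogger("gaitsole")

_FLOAT_FMT = "%.12g"


# ---------------------------------------------------------------------------
# trial-level analysis
# ---------------------------------------------------------------------------


def analyze_trial(trial: TrialRecording,
                  cfg: SegmentationConfig = SegmentationConfig(), *,
                  stride_mode: str = "zupt", speed_mode: str = "cycle"):
    """Full single-trial chain: phases, support, TUG windows, parameters.

    Returns ``(params, artifacts, qc)`` where ``artifacts`` holds the
    intermediate phase/support/cycle/TUG objects and ``qc`` counts
    both-feet-swing frames and clamped stride lengths.
    """
    trial = trial.aligned()
    fs = trial.fs
    counts_l = preprocess_and_count(trial.left, cfg)
    counts_r = preprocess_and_count(trial.right, cfg)
    phases_l = detect_phases(counts_l, fs, cfg, side="left")
    phases_r = detect_phases(counts_r, fs, cfg, side="right")
    support = classify_support(phases_l, phases_r)
    tug = segment_tug(trial, phases_l, phases_r, cfg)

    ws, we = round(tug.walking[0] * fs), round(tug.walking[1] * fs)
    cycles_l = cycles_in_window(extract_cycles(phases_l), *tug.walking, fs)
    cycles_r = cycles_in_window(extract_cycles(phases_r), *tug.walking, fs)

    if stride_mode == "zupt":
        cycles_l = estimate_stride_lengths(trial.left.accel[:, 0], cycles_l, fs)
        cycles_r = estimate_stride_lengths(trial.right.accel[:, 0], cycles_r, fs)
    elif stride_mode == "track":
        for cycles in (cycles_l, cycles_r):
            if cycles:
                stride = 2.0 * trial.meta.track_length_m / (len(cycles) + 1)
                for c in cycles:
                    c.stride_length_m = stride
    else:
        raise ConfigError(f"unknown stride_mode {stride_mode!r}")

    support_walk = clip_support(support, ws, we)
    params = compute_parameter_set(
        tug, cycles_l, cycles_r, support_walk, trial.meta.affected_side, fs,
        speed_mode=speed_mode, track_length_m=trial.meta.track_length_m)
    qc = {
        "none_support_frames": int(sum(s.end_idx - s.start_idx
                                       for s in support_walk if s.kind == "none")),
        "clamped_strides": int(sum(c.stride_clamped for c in cycles_l + cycles_r)),
        "step_count": tug.step_count,
        "n_cycles_left": len(cycles_l),
        "n_cycles_right": len(cycles_r),
    }
    artifacts = {
        "phases_left": phases_l, "phases_right": phases_r, "support": support,
        "tug": tug, "cycles_left": cycles_l, "cycles_right": cycles_r,
    }
    return params, artifacts, qc


# ---------------------------------------------------------------------------
# configuration files and provenance
# ---------------------------------------------------------------------------


def _dataclass_from_dict(cls, d: dict, name: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - valid
    if unknown:
        raise ConfigError(f"unknown {name} field(s): {', '.join(sorted(unknown))}")
    return cls(**d)


def gait_config_from_dict(d: dict) -> GaitConfig:
    return _dataclass_from_dict(GaitConfig, d, "gait config")


def cohort_config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    for key in ("patient_base", "control_base"):
        if key in d and isinstance(d[key], dict):
            d[key] = gait_config_from_dict(d[key])
    if "score_models" in d and isinstance(d["score_models"], dict):
        d["score_models"] = {
            scale: ScoreModel(**spec) if isinstance(spec, dict) else spec
            for scale, spec in d["score_models"].items()
        }
    return _dataclass_from_dict(CohortConfig, d, "cohort config")


def load_config(path: str):
    """Load a YAML simulation config; ``kind: cohort`` or ``kind: trial``."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "kind" not in raw:
        raise ConfigError(f"{path}: config must be a mapping with a 'kind' key")
    kind = raw.pop("kind")
    if kind == "cohort":
        return cohort_config_from_dict(raw)
    if kind == "trial":
        return gait_config_from_dict(raw)
    raise ConfigError(f"{path}: kind must be 'cohort' or 'trial', got {kind!r}")


def _config_hash(obj) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(type(o))

    payload = json.dumps(dataclasses.asdict(obj), sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _provenance_line(config_hash: str, seed) -> str:
    return f"# gaitsole {__version__} config_sha256={config_hash} seed={seed}"


def _write_csv(df: pd.DataFrame, path: str, provenance: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(provenance + "\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def ground_truth_to_dict(truth: GroundTruth) -> dict:
    return {
        "fs": truth.fs,
        "stance_intervals": {s: [list(iv) for iv in truth.stance_intervals[s]]
                             for s in ("left", "right")},
        "onsets": {s: truth.onsets[s].tolist() for s in ("left", "right")},
        "toeoffs": {s: truth.toeoffs[s].tolist() for s in ("left", "right")},
        "cycles": {s: [dataclasses.asdict(c) for c in truth.cycles[s]]
                   for s in ("left", "right")},
        "sit_to_stand": list(truth.sit_to_stand),
        "walking": list(truth.walking),
        "tug": list(truth.tug),
        "step_count": truth.step_count,
        "duration_s": truth.duration_s,
    }


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def run_simulate(config, out_dir: str, seed: Optional[int] = None) -> str:
    """Write a synthetic cohort (or single trial) to ``out_dir``."""
    t0 = time.perf_counter()
    os.makedirs(out_dir, exist_ok=True)
    if isinstance(config, str):
        config = load_config(config)
    chash = _config_hash(config)
    if seed is None:
        seed = config.seed

    if isinstance(config, GaitConfig):
        trial, truth = simulate_tug_trial(config, seed=seed)
        tdir = os.path.join(out_dir, "trial")
        write_trial(trial, tdir)
        with open(os.path.join(tdir, "ground_truth.json"), "w", encoding="utf-8") as fh:
            json.dump(ground_truth_to_dict(truth), fh, indent=1)
    else:
        trials, records, truths = simulate_cohort(config, seed=seed)
        manifest_rows, truth_rows = [], []
        for trial, rec, truth in zip(trials, records, truths):
            tdir = os.path.join(out_dir, "trials", rec.subject_id)
            write_trial(trial, tdir)
            with open(os.path.join(tdir, "ground_truth.json"), "w",
                      encoding="utf-8") as fh:
                json.dump(ground_truth_to_dict(truth), fh, indent=1)
            scores = rec.scores.as_dict() if rec.scores else {
                "mmse": None, "mbi": None, "fma_uex": None, "fma_lex": None}
            manifest_rows.append({
                "subject_id": rec.subject_id, "group": rec.group,
                "affected_side": rec.affected_side, **scores,
                "trial_dir": f"trials/{rec.subject_id}",
            })
            truth_rows.append({"subject_id": rec.subject_id, "group": rec.group,
                               "affected_side": rec.affected_side, **scores,
                               **rec.params.as_dict()})
        write_manifest(manifest_rows, os.path.join(out_dir, "manifest.csv"))
        _write_csv(pd.DataFrame(truth_rows), os.path.join(out_dir, "cohort_truth.csv"),
                   _provenance_line(chash, seed))

    with open(os.path.join(out_dir, "provenance.json"), "w", encoding="utf-8") as fh:
        json.dump({"tool": "gaitsole", "version": __version__,
                   "config_sha256": chash, "seed": seed}, fh, indent=2, sort_keys=True)
    log.info("simulate: wrote %s in %.2fs", out_dir, time.perf_counter() - t0)
    return out_dir


def _phase_rows(artifacts) -> pd.DataFrame:
    rows = [
        {"side": p.side, "phase": p.phase, "start_idx": p.start_idx,
         "end_idx": p.end_idx, "duration_s": p.duration_s}
        for key in ("phases_left", "phases_right") for p in artifacts[key]
    ]
    return pd.DataFrame(rows)


def _cycle_rows(artifacts) -> pd.DataFrame:
    rows = [
        {"side": c.side, "start_idx": c.start_idx, "end_idx": c.end_idx,
         "stance_s": c.stance_s, "swing_s": c.swing_s, "cycle_s": c.cycle_s,
         "stride_length_m": c.stride_length_m, "stride_clamped": c.stride_clamped}
        for key in ("cycles_left", "cycles_right") for c in artifacts[key]
    ]
    return pd.DataFrame(rows)


def run_extract(in_dir: str, out_dir: str,
                cfg: SegmentationConfig = SegmentationConfig(), *,
                stride_mode: str = "zupt", speed_mode: str = "cycle") -> str:
    """Extract one parameter row per trial listed in ``in_dir/manifest.csv``.

    A trial failing TUG segmentation yields a missing-value row plus a QC
    flag; the cohort continues.
    """
    t0 = time.perf_counter()
    os.makedirs(out_dir, exist_ok=True)
    manifest = read_manifest(os.path.join(in_dir, "manifest.csv"))
    chash = _config_hash(cfg)
    prov = _provenance_line(chash, "na")

    rows = []
    for _, m in manifest.iterrows():
        sid = str(m["subject_id"])
        tdir = os.path.join(in_dir, str(m["trial_dir"]))
        sdir = os.path.join(out_dir, sid)
        os.makedirs(sdir, exist_ok=True)
        trial = load_trial_dir(tdir)
        try:
            params, artifacts, qc = analyze_trial(
                trial, cfg, stride_mode=stride_mode, speed_mode=speed_mode)
            qc["segmentation_failed"] = False
            _write_csv(_phase_rows(artifacts), os.path.join(sdir, "phases.csv"), prov)
            _write_csv(_cycle_rows(artifacts), os.path.join(sdir, "cycles.csv"), prov)
            _write_csv(pd.DataFrame(
                [{"kind": s.kind, "start_idx": s.start_idx, "end_idx": s.end_idx}
                 for s in artifacts["support"]]),
                os.path.join(sdir, "support.csv"), prov)
            tug = artifacts["tug"]
            with open(os.path.join(sdir, "tug.json"), "w", encoding="utf-8") as fh:
                json.dump({"sit_to_stand": list(tug.sit_to_stand),
                           "walking": list(tug.walking), "tug": list(tug.tug),
                           "step_count": tug.step_count}, fh, indent=2)
        except SegmentationError as exc:
            log.warning("extract: %s failed segmentation: %s", sid, exc)
            params = GaitParameterSet()
            qc = {"segmentation_failed": True, "error": str(exc)}
        with open(os.path.join(sdir, "qc.json"), "w", encoding="utf-8") as fh:
            json.dump(qc, fh, indent=2, sort_keys=True)
        rows.append({"subject_id": sid, **params.as_dict()})

    _write_csv(pd.DataFrame(rows, columns=["subject_id", *PARAMETER_REGISTRY]),
               os.path.join(out_dir, "parameters.csv"), prov)
    log.info("extract: %d trials in %.2fs", len(rows), time.perf_counter() - t0)
    return out_dir


def records_from_tables(params_df: pd.DataFrame,
                        manifest_df: pd.DataFrame) -> list[SubjectRecord]:
    """Join a parameters table with a cohort manifest into SubjectRecords."""
    merged = manifest_df.merge(params_df, on="subject_id", how="inner",
                               validate="one_to_one")
    records = []
    for _, row in merged.iterrows():
        scores = ClinicalScores(
            mmse=row.get("mmse"), mbi=row.get("mbi"),
            fma_uex=row.get("fma_uex"), fma_lex=row.get("fma_lex"))
        if all(getattr(scores, k) is None for k in ("mmse", "mbi", "fma_uex", "fma_lex")):
            scores = None
        records.append(SubjectRecord(
            subject_id=str(row["subject_id"]), group=row["group"],
            affected_side=row["affected_side"], scores=scores,
            params=GaitParameterSet.from_dict(
                {k: row[k] for k in PARAMETER_REGISTRY})))
    return records


def run_analyze(parameters_csv: str, manifest_csv: str, out_dir: str, *,
                plots: bool = False, pooled: bool = False) -> str:
    """Write group_comparison.csv, scale_correlations.csv and outlier_refits.csv."""
    t0 = time.perf_counter()
    os.makedirs(out_dir, exist_ok=True)
    params_df = pd.read_csv(parameters_csv, comment="#")
    manifest_df = read_manifest(manifest_csv)
    records = records_from_tables(params_df, manifest_df)
    prov = _provenance_line(_config_hash(SegmentationConfig()), "na")

    comparison = compare_groups(records, pooled=pooled)
    _write_csv(comparison, os.path.join(out_dir, "group_comparison.csv"), prov)

    try:
        corr = correlate_scales(records)
    except GaitsoleError as exc:
        log.warning("analyze: correlation step skipped: %s", exc)
        corr = None
    if corr is not None:
        _write_csv(corr, os.path.join(out_dir, "scale_correlations.csv"), prov)
        refits = _outlier_refits(records, corr)
        _write_csv(refits, os.path.join(out_dir, "outlier_refits.csv"), prov)
        if plots:
            _scatter_plots(records, corr, out_dir)
    log.info("analyze: done in %.2fs", time.perf_counter() - t0)
    return out_dir


def _outlier_refits(records, corr: pd.DataFrame) -> pd.DataFrame:
    patients = [r for r in records if r.group == "patient" and r.scores is not None]
    rows = []
    for _, row in corr.iterrows():
        if not np.isfinite(row.get("r_squared", math.nan)):
            continue
        scale = row["scale"].lower()
        x = np.array([getattr(r.params, row["parameter"]) for r in patients])
        y = np.array([getattr(r.scores, scale) if getattr(r.scores, scale) is not None
                      else math.nan for r in patients])
        keep = np.isfinite(x) & np.isfinite(y)
        if keep.sum() < 4:
            continue
        res = refit_without_outlier(x[keep], y[keep],
                                    parameter=row["parameter"], scale=scale)
        rows.append({
            "parameter": res.parameter, "scale": scale.upper(), "n": res.n,
            "r_squared": res.r_squared, "slope": res.slope,
            "intercept": res.intercept, "excluded_index": res.excluded_index,
            "excluded_subject": patients[int(np.flatnonzero(keep)[res.excluded_index])].subject_id,
            "r_squared_excluded": res.r_squared_excluded,
        })
    return pd.DataFrame(rows)


def _scatter_plots(records, corr: pd.DataFrame, out_dir: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    patients = [r for r in records if r.group == "patient" and r.scores is not None]
    plot_dir = os.path.join(out_dir, "plots")
    os.makedirs(plot_dir, exist_ok=True)
    for _, row in corr[corr["significant"] == True].iterrows():  # noqa: E712
        scale = row["scale"].lower()
        x = np.array([getattr(r.params, row["parameter"]) for r in patients])
        y = np.array([getattr(r.scores, scale) if getattr(r.scores, scale) is not None
                      else math.nan for r in patients])
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.scatter(x, y, s=25)
        if np.isfinite(row["slope"]):
            xs = np.linspace(np.nanmin(x), np.nanmax(x), 2)
            ax.plot(xs, row["intercept"] + row["slope"] * xs, "r-",
                    label=f"y = {row['slope']:.2f}x + {row['intercept']:.2f}")
            ax.legend(fontsize=7)
        ax.set_xlabel(row["parameter"])
        ax.set_ylabel(row["scale"])
        ax.set_title(f"R² = {row['r_squared']:.3f}", fontsize=9)
        fig.tight_layout()
        fig.savefig(os.path.join(plot_dir, f"{row['parameter']}__{scale}.png"), dpi=110)
        plt.close(fig)
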