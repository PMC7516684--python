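"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately written in the most direct style
possible (per-frame loops, textbook sums) and stays independent of the
library code paths it checks.
"""

from __future__ import annotations

import math

import numpy as np

from gaitsole.segmentation import PhaseInterval


def brute_force_counts(pressure: np.ndarray, width: int, threshold: float) -> np.ndarray:
    """Frame-by-frame shrinking-window median + inclusive threshold count."""
    n, c = pressure.shape
    half = width // 2
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        med = np.median(pressure[lo:hi], axis=0)
        counts[i] = int(np.sum(med >= threshold))
    return counts


def brute_force_debounce(counts: np.ndarray, fs: float, min_phase_s: float) -> list:
    """Label-array merge oracle: repeatedly flip the shortest short run.

    Operates on a per-frame stance/swing label array, re-deriving runs
    from scratch each iteration; returns [(start, end, is_stance), ...].
    """
    labels = (np.asarray(counts) > 0).astype(int)

    def runs(lab):
        out = []
        s = 0
        for i in range(1, len(lab) + 1):
            if i == len(lab) or lab[i] != lab[s]:
                out.append((s, i, bool(lab[s])))
                s = i
        return out

    while True:
        r = runs(labels)
        if len(r) <= 1:
            break
        durations = [(b - a) / fs for a, b, _ in r]
        short = [i for i, d in enumerate(durations) if d < min_phase_s]
        if not short:
            break
        i = min(short, key=lambda j: (durations[j], j))
        a, b, v = r[i]
        labels[a:b] = 1 - int(v)
    return runs(labels)


def brute_force_support(phases_left, phases_right) -> list:
    """Per-frame joint-state classification then run-length encoding."""
    n = phases_left[-1].end_idx

    def stance_mask(phases):
        m = np.zeros(n, dtype=bool)
        for p in phases:
            if p.phase == "stance":
                m[p.start_idx:p.end_idx] = True
        return m

    left, right = stance_mask(phases_left), stance_mask(phases_right)
    kinds = []
    for i in range(n):
        if left[i] and right[i]:
            kinds.append("double")
        elif left[i]:
            kinds.append("single_left")
        elif right[i]:
            kinds.append("single_right")
        else:
            kinds.append("none")
    out = []
    s = 0
    for i in range(1, n + 1):
        if i == n or kinds[i] != kinds[s]:
            out.append((kinds[s], s, i))
            s = i
    return out


def random_phase_tiling(rng: np.random.Generator, side: str, n: int,
                        fs: float = 100.0) -> list:
    """A random alternating swing/stance tiling of [0, n)."""
    phases = []
    pos = 0
    current = "stance" if rng.random() < 0.5 else "swing"
    while pos < n:
        length = int(rng.integers(1, 15))
        end = min(pos + length, n)
        phases.append(PhaseInterval(side=side, phase=current,
                                    start_idx=pos, end_idx=end, fs=fs))
        current = "swing" if current == "stance" else "stance"
        pos = end
    return phases


def welch_oracle(a, b) -> tuple[float, float, float]:
    """Welch statistic, Welch-Satterthwaite df and two-sided p, closed form."""
    from scipy.stats import t as t_dist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
    t_stat = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (na - 1) + vb ** 2 / (nb - 1))
    p = 2.0 * t_dist.sf(abs(t_stat), df)
    return t_stat, df, p


def pearson_oracle(x, y) -> tuple[float, float, float]:
    """Textbook sums: r, slope and intercept of y on x."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    r = (n * sxy - sx * sy) / math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return r, slope, intercept


def outlier_index_oracle(x, y) -> int:
    """Index with max |internally studentized residual| via statsmodels."""
    import statsmodels.api as sm
    from statsmodels.stats.outliers_influence import OLSInfluence

    model = sm.OLS(np.asarray(y, float), sm.add_constant(np.asarray(x, float))).fit()
    resid = OLSInfluence(model).resid_studentized_internal
    return int(np.argmax(np.abs(resid)))


def detected_boundaries_s(phases, walking: tuple[float, float], fs: float) -> np.ndarray:
    """Detected phase-transition times (s) inside a walking window."""
    edges = np.array(sorted({p.start_idx for p in phases[1:]})) / fs
    return edges[(edges >= walking[0] - 0.05) & (edges <= walking[1] + 0.05)]


def transition_hit_fraction(truth, phases_by_side: dict, tol_s: float = 0.02) -> tuple[int, int]:
    """(hits, total) of truth walking transitions matched within tol by detection."""
    hits = total = 0
    for side in ("left", "right"):
        det = detected_boundaries_s(phases_by_side[side], truth.walking, truth.fs)
        for t in truth.transitions(side):
            total += 1
            if det.size and np.min(np.abs(det - t)) <= tol_s:
                hits += 1
    return hits, total
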