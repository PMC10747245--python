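"""Agreement statistics for method-comparison studies of gait waveforms.

Implements the battery used to validate a markerless pipeline against a
marker-based reference: mean absolute error (MAE) with a parametric 95%
confidence interval, the coefficient of multiple correlation (CMC) for
waveform-shape similarity between measurement protocols, the one-way
random-effects average-measures intraclass correlation ICC(1,k) for
trial-to-trial reproducibility, Pearson correlation, paired t-tests,
and the standard interpretation bands for each metric.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def mae(ai: np.ndarray, ref: np.ndarray) -> float:
    """Mean absolute error between two equal-length waveforms (degrees)."""
    ai = np.asarray(ai, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if ai.shape != ref.shape:
        raise ValueError(f"waveform shapes differ: {ai.shape} vs {ref.shape}")
    if not (np.all(np.isfinite(ai)) and np.all(np.isfinite(ref))):
        raise ValueError("waveforms contain non-finite points")
    return float(np.mean(np.abs(ai - ref)))


def mae_ci(per_participant_maes, confidence: float = 0.95) -> tuple[float, float, float]:
    """Mean and t-based confidence interval of per-participant MAEs.

    Returns (mean, ci_low, ci_high) using mean +/- t_{1-a/2, n-1} * SE.
    """
    x = np.asarray(per_participant_maes, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("confidence interval requires at least 2 values")
    m = float(np.mean(x))
    se = float(np.std(x, ddof=1)) / np.sqrt(n)
    t = float(sps.t.ppf(0.5 + confidence / 2, n - 1))
    return m, m - t * se, m + t * se


def cmc(waveforms: np.ndarray) -> float:
    """Coefficient of multiple correlation across F protocols over one cycle.

    ``waveforms`` is an (F, T) array: F >= 2 protocols (e.g. markerless
    and reference) measuring the same T-point cycle.  With Y_ft the
    value of protocol f at time t, Ybar_t the across-protocol mean at t
    and Ybar the grand mean::

        CMC = sqrt(1 - [sum_ft (Y_ft - Ybar_t)^2 / (T (F-1))]
                     / [sum_ft (Y_ft - Ybar)^2 / (F T - 1)])

    Returns NaN (undefined, never clamped) when the within-time variance
    exceeds the total variance or when all waveforms are constant.
    """
    y = np.asarray(waveforms, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
        raise ValueError("waveforms must be (F, T) with F >= 2 and T >= 2")
    f, t = y.shape
    mean_t = y.mean(axis=0)
    grand = y.mean()
    # all-constant input: zero total variance up to rounding -> undefined
    if np.max(np.abs(y - grand)) <= 1e-12 * max(1.0, float(np.max(np.abs(y)))):
        return float("nan")
    num = np.sum((y - mean_t) ** 2) / (t * (f - 1))
    den = np.sum((y - grand) ** 2) / (f * t - 1)
    if den == 0:
        return float("nan")
    ratio = num / den
    if ratio > 1:
        return float("nan")
    return float(np.sqrt(1.0 - ratio))


def icc_1_3(data: np.ndarray, confidence: float = 0.95) -> tuple[float, float, float]:
    """ICC(1,k): one-way random-effects, average-measures reliability.

    ``data`` is (n_subjects, k_trials), complete, with n >= 3.  From the
    one-way ANOVA decomposition with between-subject mean square BMS and
    within-subject mean square WMS::

        ICC(1,k) = (BMS - WMS) / BMS

    The confidence interval comes from F-distribution bounds on the
    variance ratio: with F_obs = BMS/WMS,
    lower = 1 - 1/(F_obs / F_{1-a/2; n-1, n(k-1)}) and
    upper = 1 - 1/(F_obs * F_{1-a/2; n(k-1), n-1}).
    Zero between-subject variance yields a non-positive ICC, reported as
    computed (never floored).
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 2:
        raise ValueError("data must be a 2-D (subjects x trials) array")
    n, k = y.shape
    if n < 3:
        raise ValueError("ICC requires at least 3 subjects")
    if k < 2:
        raise ValueError("ICC requires at least 2 trials")
    if not np.all(np.isfinite(y)):
        raise ValueError("ICC requires a complete matrix")
    row_means = y.mean(axis=1)
    grand = y.mean()
    bms = k * np.sum((row_means - grand) ** 2) / (n - 1)
    wms = np.sum((y - row_means[:, None]) ** 2) / (n * (k - 1))
    alpha = 1 - confidence
    if wms == 0:
        icc = 1.0 if bms > 0 else float("nan")
        return icc, icc, icc
    if bms == 0:
        return -np.inf, -np.inf, -np.inf
    icc = float((bms - wms) / bms)
    f_obs = bms / wms
    fl = f_obs / sps.f.ppf(1 - alpha / 2, n - 1, n * (k - 1))
    fu = f_obs * sps.f.ppf(1 - alpha / 2, n * (k - 1), n - 1)
    return icc, float(1 - 1 / fl), float(1 - 1 / fu)


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with a two-sided p from t with n-2 df.

    Returns (NaN, NaN) when either input has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) < 3:
        raise ValueError("Pearson correlation requires n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Paired two-sided t-test; returns (t, p) with n-1 df.

    Identical inputs follow the convention t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) < 3:
        raise ValueError("paired t-test requires n >= 3")
    d = x - y
    if np.std(d, ddof=1) == 0:
        if np.mean(d) == 0:
            return 0.0, 1.0
        return float(np.sign(np.mean(d)) * np.inf), 0.0
    t, p = sps.ttest_rel(x, y)
    return float(t), float(p)


# Interpretation bands.  AE bands are closed on the right; CMC bands are
# half-open [a, b) except the top band [0.95, 1.00], which is closed.
def interpret(metric: str, value: float) -> str:
    """Map a metric value to its standard interpretation label.

    ``metric`` is one of 'AE' (absolute error, degrees), 'ICC' or 'CMC'.
    Undefined (NaN) values map to 'undefined'.
    """
    m = metric.upper()
    if not np.isfinite(value):
        return "undefined"
    if m == "AE":
        if value <= 2:
            return "good accuracy"
        if value <= 5:
            return "acceptable accuracy"
        if value <= 10:
            return "tolerable accuracy"
        return "unacceptable accuracy"
    if m == "ICC":
        if value >= 0.75:
            return "excellent"
        if value >= 0.4:
            return "fair to good"
        return "poor"
    if m == "CMC":
        if 0.95 <= value <= 1.00:
            return "excellent"
        if 0.85 <= value < 0.95:
            return "very good"
        if 0.75 <= value < 0.85:
            return "good"
        if 0.65 <= value < 0.75:
            return "moderate"
        return "poor"
    raise ValueError("metric must be one of 'AE', 'ICC', 'CMC'")
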