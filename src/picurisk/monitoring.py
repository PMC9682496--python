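"""Cardiorespiratory dynamics from continuous bedside monitoring.

Continuous vitals (heart rate, respiratory rate, pulse oximetry, blood
pressure) are sampled at 0.5 Hz; heart inter-beat intervals (RRI) arrive
beat-by-beat.  Features are computed in 30-minute windows with 50 %
overlap and stamped with the window *end* time, so each feature row
summarises the most recent half hour.

The 17 measures per window are: mean and SD of HR, RR and SO2; mean
systolic and diastolic blood pressure (non-invasive preferred, invasive
in its absence); the three pairwise lag-zero cross-correlations between
HR, RR and SO2; and six inter-beat-interval dynamics measures — sRRI
(SD of intervals), COSEn (coefficient of sample entropy), the DFA
log-variance slope over scales 4–12, the local dynamics score and
density (LDs, LDd), and a surrogate atrial-fibrillation probability.

Missing values are propagated as NaN (imputed downstream), never as
zeros.  All cardiac measures go jointly missing when the RRI quality
filter leaves fewer than 60 valid intervals in a window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Window",
    "WINDOW_S",
    "STRIDE_S",
    "MONITORING_FEATURES",
    "make_windows",
    "window_vitals_stats",
    "select_bp",
    "xcorr3",
    "filter_rri",
    "srri",
    "cosen",
    "dfa_slope",
    "local_dynamics",
    "af_probability",
    "compute_window_features",
]

WINDOW_S = 1800
STRIDE_S = 900

#: minimum valid inter-beat intervals before any cardiac dynamics measure
MIN_RRI = 60
#: at most this many (most recent) intervals enter the O(n^2) template counts
MAX_RRI_TEMPLATES = 400

MONITORING_FEATURES = [
    "mean_HR", "sd_HR", "mean_RR", "sd_RR", "mean_SO2", "sd_SO2",
    "mean_SBP", "mean_DBP",
    "xcorr_HR_RR", "xcorr_HR_SO2", "xcorr_RR_SO2",
    "sRRI", "COSEn", "DFA_slope", "LDs", "LDd", "AF_prob",
]


@dataclass(frozen=True)
class Window:
    """A 30-minute analysis window, identified by its end time."""

    t_start: int
    t_end: int

    def __post_init__(self) -> None:
        if self.t_end - self.t_start != WINDOW_S:
            raise ValueError(
                f"window must span exactly {WINDOW_S} s, got "
                f"[{self.t_start}, {self.t_end})"
            )


def make_windows(span_start: float, span_end: float) -> list[Window]:
    """Tile ``[span_start, span_end)`` with 30-min windows at 15-min stride.

    The first window ends at ``span_start + 1800``; a trailing partial
    window is dropped.  An empty or too-short span yields an empty list.
    """
    start = int(span_start)
    end = int(span_end)
    out: list[Window] = []
    t_end = start + WINDOW_S
    while t_end <= end:
        out.append(Window(t_end - WINDOW_S, t_end))
        t_end += STRIDE_S
    return out


def window_vitals_stats(values: np.ndarray, *, expected: int = 900,
                        min_coverage: float = 0.5) -> tuple[float, float]:
    """Mean and sample SD of one channel's samples within a window.

    Returns ``(nan, nan)`` when the fraction of valid (finite) samples
    relative to ``expected`` (900 at 0.5 Hz) is below ``min_coverage``.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < min_coverage * expected:
        return (math.nan, math.nan)
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return (mean, sd)


def select_bp(nibp_sys: np.ndarray, nibp_dia: np.ndarray,
              ibp_sys: np.ndarray, ibp_dia: np.ndarray) -> tuple[float, float]:
    """Window-mean systolic/diastolic pressure, non-invasive preferred.

    Any NIBP value held or cycled within the window wins; invasive
    pressure is used only in its absence; otherwise both are missing.
    """
    for sys_v, dia_v in ((nibp_sys, nibp_dia), (ibp_sys, ibp_dia)):
        s = np.asarray(sys_v, dtype=float)
        d = np.asarray(dia_v, dtype=float)
        s = s[np.isfinite(s)]
        d = d[np.isfinite(d)]
        if s.size or d.size:
            return (
                float(np.mean(s)) if s.size else math.nan,
                float(np.mean(d)) if d.size else math.nan,
            )
    return (math.nan, math.nan)


def _pearson(a: np.ndarray, b: np.ndarray, min_n: int) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < min_n:
        return math.nan
    x, y = a[ok], b[ok]
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return math.nan
    r = float(np.corrcoef(x, y)[0, 1])
    return min(1.0, max(-1.0, r))


def xcorr3(hr: np.ndarray, rr: np.ndarray, so2: np.ndarray,
           *, min_n: int = 30) -> tuple[float, float, float]:
    """Lag-zero Pearson correlations (HR·RR, HR·SO2, RR·SO2).

    Series must be aligned on the common 2-s grid.  Each correlation is
    missing below ``min_n`` pairwise-complete samples or when either
    channel has zero variance.
    """
    hr = np.asarray(hr, dtype=float)
    rr = np.asarray(rr, dtype=float)
    so2 = np.asarray(so2, dtype=float)
    if not (hr.shape == rr.shape == so2.shape):
        raise ValueError("xcorr3 requires equally aligned series")
    return (
        _pearson(hr, rr, min_n),
        _pearson(hr, so2, min_n),
        _pearson(rr, so2, min_n),
    )


def filter_rri(rri_ms: np.ndarray, *, lo: float = 250.0, hi: float = 2000.0,
               ratio_lo: float = 0.6, ratio_hi: float = 1.8) -> np.ndarray:
    """Plausibility filter for inter-beat intervals within a window.

    Intervals outside [250, 2000] ms are removed, as are intervals whose
    ratio to the previously *retained* interval falls outside
    [0.6, 1.8].  Low-quality segments (ectopy, noise, missed beats) are
    thereby excluded from the cardiac dynamics measures.
    """
    x = np.asarray(rri_ms, dtype=float)
    x = x[np.isfinite(x)]
    x = x[(x >= lo) & (x <= hi)]
    # sequential rule: each interval is compared to the previous *retained*
    # one.  Dropping only the first violator per pass keeps the scan
    # vectorised while reproducing the sequential semantics exactly.
    while x.size >= 2:
        ratio = x[1:] / x[:-1]
        bad = np.nonzero((ratio < ratio_lo) | (ratio > ratio_hi))[0]
        if bad.size == 0:
            break
        x = np.delete(x, bad[0] + 1)
    return x


def srri(rri_ms: np.ndarray) -> float:
    """Sample SD (n-1) of valid inter-beat intervals, in ms."""
    x = np.asarray(rri_ms, dtype=float)
    if x.size < MIN_RRI:
        return math.nan
    return float(np.std(x, ddof=1))


def _template_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Ordered-pair template match counts (B for length m, A for m+1).

    Templates of both lengths start at i = 0..N-m-1 so the counts are
    drawn from the same index set; self-matches are excluded.  Matching
    is Chebyshev distance <= r.  Counts are over unordered pairs i<j.
    """
    n = x.size
    nt = n - m
    if nt < 2:
        return (0, 0)
    # pairwise scalar closeness, vectorised; m == 1 in this package
    close = np.abs(x[:, None] - x[None, :]) <= r
    b_mat = close[:nt, :nt].copy()
    for k in range(1, m):
        b_mat &= close[k:k + nt, k:k + nt]
    a_mat = b_mat & close[m:m + nt, m:m + nt]
    iu = np.triu_indices(nt, k=1)
    return int(b_mat[iu].sum()), int(a_mat[iu].sum())


def cosen(rri_ms: np.ndarray, *, m: int = 1, r: float = 30.0) -> float:
    """Coefficient of sample entropy of inter-beat intervals (nats).

    COSEn = -ln(A/B) + ln(2r) - ln(mean RRI), where B and A are the
    numbers of template pairs of length m and m+1 within Chebyshev
    tolerance r (ms), self-matches excluded.  The two correction terms
    make the entropy estimate comparable across tolerances and heart
    rates, which is what suits short inter-beat series.  Missing when
    either count is zero.
    """
    x = np.asarray(rri_ms, dtype=float)
    if x.size < MIN_RRI:
        return math.nan
    if x.size > MAX_RRI_TEMPLATES:
        x = x[-MAX_RRI_TEMPLATES:]
    b, a = _template_counts(x, m, r)
    if a == 0 or b == 0:
        return math.nan
    return -math.log(a / b) + math.log(2.0 * r) - math.log(float(np.mean(x)))


def dfa_slope(rri_ms: np.ndarray, *, scales: tuple[int, int] = (4, 12)) -> float:
    """Slope of log detrended-fluctuation variance vs log scale.

    First-order DFA: the mean-centred series is integrated; for each
    integer scale n in [4, 12] the profile is partitioned into
    floor(N/n) non-overlapping boxes, each box is linearly detrended,
    and F^2(n) is the mean squared residual over all used points.  The
    returned slope is the least-squares slope of ln F^2(n) on ln n —
    twice the conventional DFA exponent alpha (white noise -> 1.0,
    integrated white noise -> 3.0).
    """
    x = np.asarray(rri_ms, dtype=float)
    lo, hi = scales
    if x.size < hi * lo:  # need at least 4 boxes at the largest scale
        return math.nan
    y = np.cumsum(x - x.mean())
    log_n, log_f2 = [], []
    for n in range(lo, hi + 1):
        k = y.size // n
        if k < 1:
            continue
        boxes = y[: k * n].reshape(k, n)
        t = np.arange(n, dtype=float)
        t_c = t - t.mean()
        denom = float(np.dot(t_c, t_c))
        slope = boxes @ t_c / denom
        resid = boxes - boxes.mean(axis=1, keepdims=True) - slope[:, None] * t_c
        f2 = float(np.mean(resid ** 2))
        if f2 <= 0.0:
            return math.nan
        log_n.append(math.log(n))
        log_f2.append(math.log(f2))
    if len(log_n) < 2:
        return math.nan
    coef = np.polyfit(log_n, log_f2, 1)
    return float(coef[0])


def local_dynamics(rri_ms: np.ndarray, *, r: float = 30.0,
                   crowd_frac: float = 0.2) -> tuple[float, float]:
    """Local dynamics score and density of inter-beat intervals.

    Consecutive intervals are embedded as points (RRI_i, RRI_{i+1}); for
    each point the number of other points within Chebyshev distance r is
    counted.  LDd is the fraction of points matching *no* other point;
    LDs is the fraction matching very many — more than ``crowd_frac`` of
    all points.  Together they describe whether the rhythm lives on a
    few repeated patterns or wanders without recurrence.
    """
    x = np.asarray(rri_ms, dtype=float)
    if x.size < MIN_RRI:
        return (math.nan, math.nan)
    if x.size > MAX_RRI_TEMPLATES:
        x = x[-MAX_RRI_TEMPLATES:]
    pts = np.column_stack([x[:-1], x[1:]])
    n = pts.shape[0]
    d = np.maximum(
        np.abs(pts[:, 0][:, None] - pts[:, 0][None, :]),
        np.abs(pts[:, 1][:, None] - pts[:, 1][None, :]),
    )
    near = d <= r
    np.fill_diagonal(near, False)
    counts = near.sum(axis=1)
    ldd = float(np.mean(counts == 0))
    lds = float(np.mean(counts > crowd_frac * n))
    return (lds, ldd)


#: default surrogate AF-probability logistic coefficients
AF_COEF = {"a_cosen": 1.0, "b_cv": 5.0, "intercept": -1.0}


def af_probability(rri_ms: np.ndarray, *, coef: dict | None = None) -> float:
    """Surrogate probability of atrial fibrillation from RRI dynamics.

    AF produces an erratic, high-entropy, high-variability rhythm, so
    the surrogate is logistic(a*COSEn + b*(sRRI/mean RRI) + c) with
    documented default coefficients.  It is monotonically increasing in
    COSEn at fixed coefficient of variation and stays in [0, 1].  The
    interface is stable so a published classifier can be substituted.
    """
    c = dict(AF_COEF)
    if coef:
        c.update(coef)
    x = np.asarray(rri_ms, dtype=float)
    if x.size < MIN_RRI:
        return math.nan
    entropy = cosen(x)
    sd = srri(x)
    if not (math.isfinite(entropy) and math.isfinite(sd)):
        return math.nan
    z = c["a_cosen"] * entropy + c["b_cv"] * (sd / float(np.mean(x))) + c["intercept"]
    return float(1.0 / (1.0 + math.exp(-z)))


def compute_window_features(hr: np.ndarray, rr: np.ndarray, so2: np.ndarray,
                            nibp_sys: np.ndarray, nibp_dia: np.ndarray,
                            ibp_sys: np.ndarray, ibp_dia: np.ndarray,
                            rri_ms: np.ndarray,
                            cardiac_dynamics: bool = True) -> dict[str, float]:
    """All 17 monitoring measures for one 30-minute window.

    ``hr``/``rr``/``so2`` are the aligned 0.5 Hz samples falling in the
    window (NaN for dropouts); blood-pressure arrays carry whatever
    held/cycled values fall in the window; ``rri_ms`` the raw intervals.
    """
    out: dict[str, float] = {}
    out["mean_HR"], out["sd_HR"] = window_vitals_stats(hr)
    out["mean_RR"], out["sd_RR"] = window_vitals_stats(rr)
    out["mean_SO2"], out["sd_SO2"] = window_vitals_stats(so2)
    out["mean_SBP"], out["mean_DBP"] = select_bp(nibp_sys, nibp_dia,
                                                 ibp_sys, ibp_dia)
    out["xcorr_HR_RR"], out["xcorr_HR_SO2"], out["xcorr_RR_SO2"] = xcorr3(
        hr, rr, so2)
    valid = filter_rri(rri_ms) if cardiac_dynamics else np.zeros(0)
    if valid.size < MIN_RRI:
        for k in ("sRRI", "COSEn", "DFA_slope", "LDs", "LDd", "AF_prob"):
            out[k] = math.nan
    else:
        out["sRRI"] = srri(valid)
        out["COSEn"] = cosen(valid)
        out["DFA_slope"] = dfa_slope(valid)
        out["LDs"], out["LDd"] = local_dynamics(valid)
        out["AF_prob"] = af_probability(valid)
    return out
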