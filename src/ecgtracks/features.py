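"""Time-series feature catalogue for the gradient-boosting track.

Features follow the ``group__param_value`` naming convention of the tsfresh
library, so importance scores aggregate naturally into groups (everything
before the first double underscore).  The catalogue mirrors an "efficient"
feature set with the expensive families removed: no entropy features, no
matrix profile, no CWT peak counting, no partial autocorrelation, no
aggregated linear trend, and no augmented Dickey-Fuller statistics.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy import stats

#: Family name fragments that must never appear in a column name.
EXCLUDED_FAMILIES = (
    "entropy",
    "matrix_profile",
    "number_cwt_peaks",
    "partial_autocorrelation",
    "agg_linear_trend",
    "augmented_dickey_fuller",
)


def _safe(x):
    return np.asarray(x, dtype=float).ravel()


def _autocorr(x, lag):
    n = x.size
    if lag >= n:
        return np.nan
    v = x.var()
    if v == 0:
        return np.nan
    xm = x - x.mean()
    return float(np.dot(xm[: n - lag], xm[lag:]) / ((n - lag) * v))


def _ricker(points, a):
    t = np.arange(points) - (points - 1) / 2.0
    amp = 2 / (np.sqrt(3 * a) * np.pi**0.25)
    return amp * (1 - (t / a) ** 2) * np.exp(-(t**2) / (2 * a**2))


def _lempel_ziv(x, bins):
    seq = np.digitize(x, np.linspace(x.min(), x.max(), bins + 1)[1:-1])
    n = seq.size
    seen = set()
    words = 0
    i = 0
    while i < n:
        j = i + 1
        while j <= n and tuple(seq[i:j]) in seen:
            j += 1
        seen.add(tuple(seq[i:j]))
        words += 1
        i = j
    return words / n


def _change_quantiles(x, ql, qh, isabs, f_agg):
    if ql >= qh:
        return 0.0
    lo, hi = np.quantile(x, [ql, qh])
    inside = (x >= lo) & (x <= hi)
    sel = inside[:-1] & inside[1:]
    if not np.any(sel):
        return 0.0
    d = np.diff(x)[sel]
    if isabs:
        d = np.abs(d)
    return float(d.mean() if f_agg == "mean" else d.var())


def _number_peaks(x, n):
    if x.size < 2 * n + 1:
        return 0
    core = x[n:-n]
    ok = np.ones(core.size, dtype=bool)
    for off in range(1, n + 1):
        ok &= core > x[n - off : -(n + off)]
        right = x[n + off :]
        ok &= core > right[: core.size]
    return int(ok.sum())


def extract_feature_vector(x: np.ndarray) -> dict[str, float]:
    """All catalogue features for one series; NaN marks an undefined value
    (e.g. autocorrelation of a constant series), to be imputed downstream."""
    x = _safe(x)
    n = x.size
    out: dict[str, float] = {}
    mean, std = x.mean(), x.std()
    var = std**2
    d = np.diff(x)

    out["sum_values"] = x.sum()
    out["mean"] = mean
    out["median"] = float(np.median(x))
    out["standard_deviation"] = std
    out["variance"] = var
    out["maximum"] = x.max()
    out["minimum"] = x.min()
    out["absolute_maximum"] = np.abs(x).max()
    out["abs_energy"] = float(np.dot(x, x))
    out["root_mean_square"] = float(np.sqrt(np.mean(x**2)))
    out["skewness"] = float(stats.skew(x)) if std > 0 else np.nan
    out["kurtosis"] = float(stats.kurtosis(x)) if std > 0 else np.nan
    out["variation_coefficient"] = std / mean if mean != 0 else np.nan
    out["mean_abs_change"] = float(np.abs(d).mean()) if d.size else np.nan
    out["mean_change"] = float(d.mean()) if d.size else np.nan
    out["mean_second_derivative_central"] = (
        float((x[2:] - 2 * x[1:-1] + x[:-2]).mean() / 2) if n > 2 else np.nan)
    out["count_above_mean"] = int((x > mean).sum())
    out["count_below_mean"] = int((x < mean).sum())
    out["count_above__t_0"] = float((x > 0).mean())
    out["count_below__t_0"] = float((x < 0).mean())
    out["first_location_of_maximum"] = float(np.argmax(x)) / n
    out["last_location_of_maximum"] = 1.0 - float(np.argmax(x[::-1])) / n
    out["first_location_of_minimum"] = float(np.argmin(x)) / n
    out["last_location_of_minimum"] = 1.0 - float(np.argmin(x[::-1])) / n

    for tag, m in (("above", x > mean), ("below", x < mean)):
        best = cur = 0
        for v in m:
            cur = cur + 1 if v else 0
            best = max(best, cur)
        out[f"longest_strike_{tag}_mean"] = best

    for q in (0.1, 0.2, 0.3, 0.4, 0.6, 0.7, 0.8, 0.9):
        out[f"quantile__q_{q}"] = float(np.quantile(x, q))

    for lag in range(1, 10):
        out[f"autocorrelation__lag_{lag}"] = _autocorr(x, lag)
    acfs = np.array([_autocorr(x, k) for k in range(1, min(41, n))])
    import warnings as _warnings
    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        out["agg_autocorrelation__f_agg_mean__maxlag_40"] = float(np.nanmean(acfs)) if acfs.size else np.nan
        out["agg_autocorrelation__f_agg_median__maxlag_40"] = float(np.nanmedian(acfs)) if acfs.size else np.nan
        out["agg_autocorrelation__f_agg_var__maxlag_40"] = float(np.nanvar(acfs)) if acfs.size else np.nan

    for r in (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 5.0, 6.0, 7.0, 10.0):
        out[f"ratio_beyond_r_sigma__r_{r}"] = (
            float((np.abs(x - mean) > r * std).mean()) if std > 0 else np.nan)

    seg = np.array_split(x**2, 10)
    total = float(np.sum(x**2))
    for i, s in enumerate(seg):
        out[f"energy_ratio_by_chunks__num_segments_10__segment_focus_{i}"] = (
            float(s.sum() / total) if total > 0 else np.nan)

    absx = np.abs(x)
    csum = np.cumsum(absx)
    for q in (0.1, 0.2, 0.3, 0.4, 0.6, 0.7, 0.8, 0.9):
        if csum[-1] > 0:
            out[f"index_mass_quantile__q_{q}"] = (
                float(np.searchsorted(csum, q * csum[-1]) + 1) / n)
        else:
            out[f"index_mass_quantile__q_{q}"] = np.nan

    for lo, hi in ((-1.0, 1.0), (0.0, 1.0), (-2.0, 2.0)):
        out[f"range_count__max_{hi}__min_{lo}"] = int(((x >= lo) & (x < hi)).sum())

    nperseg = min(256, n)
    freqs, pxx = sps.welch(x, nperseg=nperseg)
    for coeff in (2, 5, 8):
        out[f"spkt_welch_density__coeff_{coeff}"] = (
            float(pxx[coeff]) if coeff < pxx.size else np.nan)

    for ql in (0.0, 0.2, 0.4):
        for qh in (0.6, 0.8, 1.0):
            for isabs in (False, True):
                for f_agg in ("mean", "var"):
                    key = (f"change_quantiles__f_agg_{f_agg}__isabs_{isabs}"
                           f"__qh_{qh}__ql_{ql}")
                    out[key] = _change_quantiles(x, ql, qh, isabs, f_agg)

    fft = np.fft.rfft(x)
    for coeff in range(11):
        c = fft[coeff] if coeff < fft.size else np.nan
        out[f"fft_coefficient__attr_real__coeff_{coeff}"] = np.real(c)
        out[f"fft_coefficient__attr_imag__coeff_{coeff}"] = np.imag(c)
        out[f"fft_coefficient__attr_abs__coeff_{coeff}"] = np.abs(c)
        out[f"fft_coefficient__attr_angle__coeff_{coeff}"] = (
            np.angle(c) if np.all(np.isfinite([c])) else np.nan)
    mag = np.abs(fft)
    fidx = np.arange(mag.size)
    msum = mag.sum()
    if msum > 0:
        centroid = float((fidx * mag).sum() / msum)
        spread = float(((fidx - centroid) ** 2 * mag).sum() / msum)
        out["fft_aggregated__aggtype_centroid"] = centroid
        out["fft_aggregated__aggtype_variance"] = spread
    else:
        out["fft_aggregated__aggtype_centroid"] = np.nan
        out["fft_aggregated__aggtype_variance"] = np.nan

    for w in (2, 5, 10, 20):
        width = min(10 * w, n)
        conv = np.convolve(x, _ricker(width, w), mode="same")
        for coeff in range(5):
            pos = coeff * max(1, n // 5)
            out[f"cwt_coefficients__coeff_{coeff}__w_{w}"] = (
                float(conv[pos]) if pos < n else np.nan)

    for npk in (1, 3, 5, 10, 50):
        out[f"number_peaks__n_{npk}"] = _number_peaks(x, npk)
    for m in (-1.0, 0.0, 1.0):
        out[f"number_crossing_m__m_{m}"] = int(
            (np.diff(np.sign(x - m)) != 0).sum())

    for bins in (2, 3, 5, 10, 100):
        out[f"lempel_ziv_complexity__bins_{bins}"] = (
            _lempel_ziv(x, bins) if std > 0 else np.nan)

    for lag in (1, 2, 3):
        if n > 2 * lag:
            out[f"c3__lag_{lag}"] = float(
                np.mean(x[2 * lag :] * x[lag : n - lag] * x[: n - 2 * lag]))
            out[f"time_reversal_asymmetry_statistic__lag_{lag}"] = float(
                np.mean(x[2 * lag :] ** 2 * x[lag : n - lag]
                        - x[lag : n - lag] * x[: n - 2 * lag] ** 2))
        else:
            out[f"c3__lag_{lag}"] = np.nan
            out[f"time_reversal_asymmetry_statistic__lag_{lag}"] = np.nan

    ce = float(np.sqrt(np.dot(d, d))) if d.size else np.nan
    out["cid_ce__normalize_False"] = ce
    out["cid_ce__normalize_True"] = ce / std if std > 0 else np.nan

    for r in (0.05, 0.15, 0.25):
        out[f"symmetry_looking__r_{r}"] = float(
            np.abs(mean - np.median(x)) < r * (x.max() - x.min())
        ) if x.max() > x.min() else np.nan
        out[f"large_standard_deviation__r_{r}"] = float(
            std > r * (x.max() - x.min())) if x.max() > x.min() else np.nan

    t = np.arange(n)
    res = stats.linregress(t, x)
    for attr in ("slope", "intercept", "rvalue", "pvalue", "stderr"):
        out[f"linear_trend__attr_{attr}"] = float(getattr(res, attr))

    return out
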