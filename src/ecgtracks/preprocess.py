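"""Signal conditioning, Hamilton R-peak detection, NN-interval extraction and
the input transform for the 1D convolutional models.

The detector follows the classic Hamilton pipeline: 3–45 Hz bandpass,
differentiation, rectification, 80 ms moving-average integration, then an
adaptive threshold held between running averages of recent signal peaks and
noise peaks, a 200 ms refractory period, and a search-back pass at a lower
threshold when an expected beat is missed.  Detected peaks are refined to the
local maximum of the filtered signal within +/-40 ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import EcgRecord

#: Hamilton-pipeline constants (seconds unless noted).
INTEGRATION_WINDOW_S = 0.080
REFRACTORY_S = 0.200
THRESHOLD_COEF = 0.45  # position of the detection threshold between noise and signal peak estimates
SEARCHBACK_FRACTION = 0.5
REFINE_WINDOW_S = 0.040
PEAK_MEMORY = 8  # running averages use the last this-many peaks

#: NN normality filter: physiological RR bounds and the maximum relative
#: deviation from the running median of recent accepted intervals.
NN_RR_MIN_S = 0.3
NN_RR_MAX_S = 2.0
NN_MAX_DEVIATION = 0.5
NN_MEDIAN_WINDOW = 5


@dataclass
class BeatSeries:
    """Detected R-peaks with the derived RR and artifact-filtered NN series."""

    r_peaks: np.ndarray  # sample indices, strictly increasing
    fs: float
    rr: np.ndarray = field(default=None)  # seconds
    nn: np.ndarray = field(default=None)  # seconds, subset of rr

    def __post_init__(self) -> None:
        self.r_peaks = np.asarray(self.r_peaks, dtype=int)
        if self.r_peaks.size and np.any(np.diff(self.r_peaks) <= 0):
            raise ValueError("r_peaks must be strictly increasing")
        if self.rr is None:
            self.rr = np.diff(self.r_peaks) / self.fs
        else:
            self.rr = np.asarray(self.rr, dtype=float)
        if self.nn is None:
            self.nn = np.empty(0)
        else:
            self.nn = np.asarray(self.nn, dtype=float)


@dataclass
class Transformed1D:
    """First-order-differenced, z-scored signal for the 1D models."""

    x: np.ndarray  # (n_leads, n_samples - 1)


def bandpass(x: np.ndarray, fs: float, low: float = 3.0, high: float = 45.0) -> np.ndarray:
    """Zero-phase FIR bandpass; output length equals input length.

    The filter is a Hamming-windowed linear-phase FIR applied forward and
    backward, so the net response is zero-phase and the stopband attenuation
    is doubled.
    """
    if fs <= 2 * high:
        raise ValueError(f"fs={fs} must exceed twice the upper edge {high} Hz")
    x = np.asarray(x, dtype=float)
    numtaps = int(1.5 * fs) | 1
    taps = sps.firwin(numtaps, [low, high], pass_zero=False, fs=fs)
    padlen = min(3 * numtaps, x.shape[-1] - 1)
    return sps.filtfilt(taps, [1.0], x, padlen=padlen)


def detect_rpeaks(x: np.ndarray, fs: float) -> BeatSeries:
    """Hamilton-style QRS detection on a single-lead signal."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2 * fs:
        warnings.warn("input shorter than 2 s; returning empty beat series",
                      stacklevel=2)
        return BeatSeries(r_peaks=np.empty(0, dtype=int), fs=fs)

    filt = bandpass(x, fs)
    deriv = np.abs(np.diff(filt, prepend=filt[0]))
    win = max(1, int(round(INTEGRATION_WINDOW_S * fs)))
    feature = np.convolve(deriv, np.ones(win) / win, mode="same")

    # candidate local maxima of the integrated feature
    cand, _ = sps.find_peaks(feature, distance=max(1, int(REFRACTORY_S * fs)))
    if cand.size == 0:
        return BeatSeries(r_peaks=np.empty(0, dtype=int), fs=fs)

    sig_peaks: list[float] = []
    noise_peaks: list[float] = []
    accepted: list[int] = []
    rr_history: list[float] = []
    # initial estimates from the first two seconds
    init = feature[: int(2 * fs)]
    spk = float(np.max(init)) if init.size else float(np.max(feature))
    npk = float(np.mean(init)) if init.size else 0.0

    def threshold() -> float:
        return npk + THRESHOLD_COEF * (spk - npk)

    def mean_rr() -> float:
        return float(np.mean(rr_history[-PEAK_MEMORY:])) if rr_history else 0.0

    def accept(idx: int, height: float) -> None:
        nonlocal spk
        if accepted:
            rr_history.append((idx - accepted[-1]) / fs)
        accepted.append(idx)
        sig_peaks.append(height)
        spk = float(np.mean(sig_peaks[-PEAK_MEMORY:]))

    refractory = int(REFRACTORY_S * fs)
    missed_pool: list[tuple[int, float]] = []
    for idx in cand:
        h = feature[idx]
        if accepted and idx - accepted[-1] < refractory:
            continue
        if h > threshold():
            # search-back: if the gap since the last beat is over 1.5x the
            # running RR, revisit sub-threshold candidates at a lower bar
            if accepted and rr_history:
                gap = (idx - accepted[-1]) / fs
                if gap > 1.5 * mean_rr():
                    back = [(j, hj) for j, hj in missed_pool
                            if hj > SEARCHBACK_FRACTION * threshold()
                            and j - accepted[-1] >= refractory and idx - j >= refractory]
                    if back:
                        j, hj = max(back, key=lambda p: p[1])
                        accept(j, hj)
            accept(idx, float(h))
            missed_pool.clear()
        else:
            noise_peaks.append(float(h))
            npk = float(np.mean(noise_peaks[-PEAK_MEMORY:]))
            missed_pool.append((idx, float(h)))

    # refine each detection to the local maximum of the filtered signal
    half = int(round(REFINE_WINDOW_S * fs))
    refined = []
    for idx in accepted:
        lo, hi = max(0, idx - half), min(x.size, idx + half + 1)
        refined.append(lo + int(np.argmax(filt[lo:hi])))
    refined = sorted(set(refined))
    return BeatSeries(r_peaks=np.asarray(refined, dtype=int), fs=fs)


def extract_nn(beats: BeatSeries) -> BeatSeries:
    """Filter the RR series down to normal-to-normal (NN) intervals.

    An interval is rejected when it falls outside the physiological band
    [0.3 s, 2.0 s] or deviates by more than 50% from the running median of
    the last five accepted intervals.  Order is preserved among retained
    intervals.
    """
    if beats.r_peaks.size < 3:
        warnings.warn("fewer than 3 R-peaks; NN series is empty", stacklevel=2)
        return BeatSeries(r_peaks=beats.r_peaks, fs=beats.fs, rr=beats.rr,
                          nn=np.empty(0))
    nn: list[float] = []
    for interval in beats.rr:
        if not NN_RR_MIN_S <= interval <= NN_RR_MAX_S:
            continue
        if nn:
            med = float(np.median(nn[-NN_MEDIAN_WINDOW:]))
            if abs(interval - med) > NN_MAX_DEVIATION * med:
                continue
        nn.append(float(interval))
    return BeatSeries(r_peaks=beats.r_peaks, fs=beats.fs, rr=beats.rr,
                      nn=np.asarray(nn))


def nn_series(x: np.ndarray, fs: float) -> np.ndarray:
    """Convenience: detect R-peaks and return the NN-interval series."""
    return extract_nn(detect_rpeaks(x, fs)).nn


def transform_1d(record: EcgRecord) -> Transformed1D:
    """First-order difference, then per-lead standardisation to zero mean and
    unit variance.  Constant leads (undefined SD) map to zeros with a warning.
    """
    diff = np.diff(record.signal, axis=1)
    out = np.zeros_like(diff)
    for li in range(diff.shape[0]):
        sd = diff[li].std()
        if sd == 0:
            warnings.warn(f"lead {record.lead_names[li]} is constant; "
                          "transform yields zeros", stacklevel=2)
            continue
        out[li] = (diff[li] - diff[li].mean()) / sd
    return Transformed1D(x=out)


def prepare_window(record: EcgRecord, target_fs: float | None = None,
                   window_s: float | None = None) -> EcgRecord:
    """Resample to a common rate and crop/zero-pad to a fixed window.

    The public challenge sets mix lengths from 5 s to 30 min and rates from
    257 to 1000 Hz; batched models need a fixed shape.  Defaults: 300 Hz and
    30 s for single-lead records, 500 Hz and 10 s for multi-lead ones
    (the medians of the respective dataset styles).
    """
    if target_fs is None:
        target_fs = 300.0 if record.n_leads == 1 else 500.0
    if window_s is None:
        window_s = 30.0 if record.n_leads == 1 else 10.0
    sig = record.signal
    if record.fs != target_fs:
        n_new = int(round(record.n_samples * target_fs / record.fs))
        sig = sps.resample_poly(
            sig, int(round(target_fs)), int(round(record.fs)), axis=1
        )[:, :n_new]
    n_target = int(round(window_s * target_fs))
    if sig.shape[1] >= n_target:
        sig = sig[:, :n_target]
    else:
        sig = np.pad(sig, ((0, 0), (0, n_target - sig.shape[1])))
    return EcgRecord(
        record_id=record.record_id, signal=sig, fs=target_fs,
        lead_names=record.lead_names, labels=record.labels,
        age=record.age, sex=record.sex, source=record.source,
    )
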