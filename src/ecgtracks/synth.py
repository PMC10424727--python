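"""Synthetic annotated ECG generation.

Each heartbeat is modelled as a sum of five Gaussian bumps (P, Q, R, S, T)
placed at fixed offsets relative to the R time — a deliberately simple
morphology that is fully controllable and carries exact ground-truth R-peak
positions, so the beat detector and all three classifier tracks can be
exercised without real recordings.

Rhythm classes:

* ``sinus``  — regular rhythm, mean RR 0.8 s, small Gaussian RR jitter;
* ``af``     — atrial fibrillation: i.i.d. irregular RR intervals
  (truncated Gaussian, sigma = 0.2 * mean RR) and absent P-wave;
* ``tachy``  — sinus tachycardia, mean RR 0.45 s (~133 bpm);
* ``brady``  — sinus bradycardia, mean RR 1.2 s (50 bpm);
* ``noisy``  — sinus rhythm buried in heavy additive noise.

Baseline wander is a single 0.25 Hz sinusoid, sized so the 3–45 Hz bandpass
stage has something to remove; measurement noise is white Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
import json

import numpy as np

from .io import EcgRecord, write_record

CLASS_IDS = ("sinus", "af", "tachy", "brady", "noisy")

# (offset from R in seconds, amplitude mV, width sigma in seconds)
BEAT_TEMPLATE = {
    "P": (-0.17, 0.15, 0.025),
    "Q": (-0.035, -0.10, 0.010),
    "R": (0.0, 1.00, 0.012),
    "S": (0.035, -0.15, 0.010),
    "T": (0.30, 0.30, 0.060),
}

#: Per-lead amplitude scaling used for 12-lead records (rough limb/precordial
#: proportions; not a vectorcardiographic projection).
LEAD12_NAMES = ["I", "II", "III", "aVR", "aVL", "aVF", "V1", "V2", "V3", "V4", "V5", "V6"]
LEAD12_SCALE = np.array([0.6, 1.0, 0.5, -0.7, 0.4, 0.8, 0.5, 0.9, 1.1, 1.2, 1.0, 0.9])


@dataclass
class RhythmSpec:
    """Generation parameters for one rhythm class."""

    class_id: str
    mean_rr: float
    rr_sd: float
    rr_model: str = "gaussian"  # or "irregular"
    p_wave_present: bool = True
    noise_sd: float = 0.05  # mV
    baseline_wander_amp: float = 0.1  # mV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_id not in CLASS_IDS:
            raise ValueError(f"unknown rhythm class {self.class_id!r}")
        if not 0.3 <= self.mean_rr <= 2.0:
            raise ValueError("mean_rr must be in [0.3, 2.0] s")
        if self.rr_sd < 0:
            raise ValueError("rr_sd must be non-negative")
        if self.rr_model not in ("gaussian", "irregular"):
            raise ValueError(f"unknown rr_model {self.rr_model!r}")
        if self.rr_model == "irregular" and self.rr_sd < 0.1 * self.mean_rr:
            raise ValueError("irregular rr_model requires rr_sd >= 0.1 * mean_rr")

    @classmethod
    def for_class(cls, class_id: str, seed: int = 0, **overrides) -> "RhythmSpec":
        """Default spec for a rhythm class; keyword overrides win."""
        base = {
            "sinus": dict(mean_rr=0.80, rr_sd=0.03),
            "tachy": dict(mean_rr=0.45, rr_sd=0.02),
            "brady": dict(mean_rr=1.20, rr_sd=0.04),
            "af": dict(mean_rr=0.80, rr_sd=0.16, rr_model="irregular",
                       p_wave_present=False),
            "noisy": dict(mean_rr=0.80, rr_sd=0.03, noise_sd=0.35),
        }[class_id]
        base.update(overrides)
        return cls(class_id=class_id, seed=seed, **base)


@dataclass
class GroundTruth:
    """Exact beat annotation for a simulated record."""

    r_peak_times: np.ndarray  # seconds, strictly increasing
    rhythm_label: str

    def __post_init__(self) -> None:
        self.r_peak_times = np.asarray(self.r_peak_times, dtype=float)
        if np.any(np.diff(self.r_peak_times) <= 0):
            raise ValueError("r_peak_times must be strictly increasing")


def _draw_rr(spec: RhythmSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw ``n`` RR intervals; truncated below at 0.3 s."""
    if spec.rr_sd == 0:
        return np.full(n, spec.mean_rr)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(spec.mean_rr, spec.rr_sd, size=2 * (n - filled))
        draw = draw[draw >= 0.3][: n - filled]
        out[filled : filled + draw.size] = draw
        filled += draw.size
    return out


def simulate_record(spec: RhythmSpec, duration_s: float = 30.0, fs: float = 300.0,
                    n_leads: int = 1, record_id: str | None = None,
                    source: str = "synthetic") -> tuple[EcgRecord, GroundTruth]:
    """Simulate one annotated ECG record.

    Returns the record together with ground truth holding the exact R-bump
    centres. Deterministic for a fixed ``spec.seed``.
    """
    if not 5.0 <= duration_s <= 1800.0:
        raise ValueError("duration_s must be in [5, 1800] s")
    if not 100.0 <= fs <= 1000.0:
        raise ValueError("fs must be in [100, 1000] Hz")
    if n_leads not in (1, 12):
        raise ValueError("n_leads must be 1 or 12")

    rng = np.random.default_rng(spec.seed)
    t0 = rng.uniform(0.1, 0.4)
    max_beats = int(np.ceil((duration_s - t0) / 0.3)) + 2
    rr = _draw_rr(spec, rng, max_beats)
    r_times = t0 + np.concatenate([[0.0], np.cumsum(rr)])
    # keep every beat whose R centre lies inside the record; a boundary beat
    # simply has its T-wave truncated
    r_times = r_times[r_times <= duration_s]

    n_samples = int(round(duration_s * fs))
    t = np.arange(n_samples) / fs
    base = np.zeros(n_samples)
    # T offset shrinks for fast rhythms so waves stay inside the cycle
    mean_rr_eff = spec.mean_rr
    for name, (off, amp, sig) in BEAT_TEMPLATE.items():
        if name == "P" and not spec.p_wave_present:
            continue
        if name == "T":
            off = min(off, 0.55 * mean_rr_eff)
        if name == "P":
            off = max(off, -0.45 * mean_rr_eff)
        for rt in r_times:
            c = rt + off
            lo = max(0, int((c - 5 * sig) * fs))
            hi = min(n_samples, int((c + 5 * sig) * fs) + 1)
            if hi > lo:
                base[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - c) / sig) ** 2)

    wander = spec.baseline_wander_amp * np.sin(
        2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi)
    )
    if n_leads == 1:
        signal = base[None, :] * 1.0
        lead_names = ["I"]
    else:
        signal = LEAD12_SCALE[:, None] * base[None, :]
        lead_names = list(LEAD12_NAMES)
    signal = signal + wander[None, :]
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, size=signal.shape)

    rec = EcgRecord(
        record_id=record_id or f"{spec.class_id}_{spec.seed}",
        signal=signal, fs=fs, lead_names=lead_names,
        labels={spec.class_id}, source=source,
    )
    return rec, GroundTruth(r_peak_times=r_times, rhythm_label=spec.class_id)


def simulate_dataset(class_mix: dict[str, int], dialect: str = "cinc2017",
                     seed: int = 0, duration_s: float | None = None,
                     noise_sd: float | None = None,
                     ) -> list[tuple[EcgRecord, GroundTruth]]:
    """Simulate a labelled dataset with exact per-class counts.

    Per-record seeds are derived from the master ``seed``.  The ``cinc2017``
    dialect yields single-lead 300 Hz records (default duration 30 s, the
    dataset's median); ``cinc2020`` yields 12-lead records with sampling rate
    drawn from {257, 500, 1000} Hz (default duration 10 s).  ``duration_s``
    and ``noise_sd`` override the dialect defaults for every record.
    """
    if not class_mix or all(c == 0 for c in class_mix.values()):
        raise ValueError("class_mix must request at least one record")
    if any(c < 0 for c in class_mix.values()):
        raise ValueError("class counts must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    idx = 0
    for class_id in sorted(class_mix):
        for _ in range(class_mix[class_id]):
            rec_seed = int(rng.integers(0, 2**31 - 1))
            overrides = {} if noise_sd is None else {"noise_sd": noise_sd}
            spec = RhythmSpec.for_class(class_id, seed=rec_seed, **overrides)
            if dialect == "cinc2020":
                fs = float(rng.choice([257.0, 500.0, 1000.0]))
                dur = duration_s if duration_s is not None else 10.0
                n_leads = 12
                source = str(rng.choice(["CPSC", "PTB-XL", "G12EC"]))
            else:
                fs, n_leads, source = 300.0, 1, "synthetic"
                dur = duration_s if duration_s is not None else 30.0
            rec, gt = simulate_record(
                spec, duration_s=dur, fs=fs, n_leads=n_leads,
                record_id=f"S{idx:05d}", source=source,
            )
            out.append((rec, gt))
            idx += 1
    return out


def write_dataset(pairs, out_dir, dialect: str = "synthetic") -> Path:
    """Write simulated records as WFDB-dialect files plus a ground-truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = {}
    for rec, gt in pairs:
        write_record(rec, out_dir / rec.record_id, dialect=dialect)
        truth[rec.record_id] = {
            "r_peak_times": [round(float(x), 6) for x in gt.r_peak_times],
            "rhythm_label": gt.rhythm_label,
        }
    gt_path = out_dir / "ground_truth.json"
    gt_path.write_text(json.dumps(truth, indent=1))
    return gt_path
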