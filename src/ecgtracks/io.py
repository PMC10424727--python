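"""Reading and writing WFDB-dialect ECG records, label schemes and dataset splits.

Two public-challenge dialects are supported alongside the package's own
``synthetic`` dialect:

* ``cinc2017`` — single-lead 300 Hz recordings, four rhythm classes
  (Normal / AF / Other / Noisy) stored in a sidecar ``REFERENCE.csv``;
* ``cinc2020`` — 12-lead multi-label recordings with diagnosis codes and
  demographics embedded in header comment lines (``# Dx:``, ``# Age:``,
  ``# Sex:``).

Signals are stored as WFDB format-16 little-endian integers with a per-lead
gain (ADC units per millivolt), and converted to physical units on read.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

DIALECTS = ("cinc2017", "cinc2020", "synthetic")

#: Default ADC gain (integer units per mV) used by :func:`write_record`.
DEFAULT_GAIN = 1000.0


class FormatError(ValueError):
    """Header/signal inconsistency or malformed file."""


@dataclass
class LabelScheme:
    """Class list and raw-code normalisation for one dataset style.

    ``mode`` is ``multiclass`` (exactly one label per record, CinC-2017 style)
    or ``multilabel`` (one or more diagnosis codes, CinC-2020 style).
    ``code_map`` maps raw header/CSV codes to canonical class identifiers;
    unknown codes are dropped with a warning rather than raising, since the
    public challenge sets carry unscored codes.
    """

    mode: str
    classes: list[str]
    code_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("multiclass", "multilabel"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("classes must be unique")

    def normalize(self, raw_codes) -> set[str]:
        """Map raw codes to class ids, dropping unknown codes with a warning."""
        out: set[str] = set()
        for code in raw_codes:
            code = str(code).strip()
            if not code:
                continue
            if code in self.code_map:
                out.add(self.code_map[code])
            elif code in self.classes:
                out.add(code)
            else:
                logger.warning("dropping unknown diagnosis code %r", code)
        return out

    def index(self, cls: str) -> int:
        return self.classes.index(cls)

    @classmethod
    def cinc2017(cls) -> "LabelScheme":
        return cls(
            mode="multiclass",
            classes=["N", "A", "O", "~"],
            code_map={"N": "N", "A": "A", "O": "O", "~": "~"},
        )

    @classmethod
    def synthetic(cls, classes=("sinus", "af", "tachy", "brady")) -> "LabelScheme":
        return cls(mode="multiclass", classes=list(classes))

    @classmethod
    def synthetic_multilabel(cls, classes=("sinus", "af", "tachy", "brady")) -> "LabelScheme":
        return cls(mode="multilabel", classes=list(classes))


@dataclass
class EcgRecord:
    """One ECG recording: a leads-by-samples signal matrix in millivolts."""

    record_id: str
    signal: np.ndarray  # (n_leads, n_samples), mV
    fs: float
    lead_names: list[str]
    labels: set[str] = field(default_factory=set)
    age: int | None = None
    sex: str | None = None
    source: str = "unknown"

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        if len(self.lead_names) != self.signal.shape[0]:
            raise ValueError("lead_names length must equal n_leads")
        if self.sex is not None and self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")

    @property
    def n_leads(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def length_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class DatasetSplit:
    """A 60/20/20-style random partition of record ids."""

    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    seed: int

    def __post_init__(self) -> None:
        parts = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(p) for p in parts)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise ValueError("split parts must be pairwise disjoint")

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "train": list(self.train_ids),
                    "validation": list(self.val_ids),
                    "test": list(self.test_ids),
                    "seed": self.seed,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path) -> "DatasetSplit":
        d = json.loads(Path(path).read_text())
        return cls(d["train"], d["validation"], d["test"], d["seed"])


# ---------------------------------------------------------------------------
# WFDB-dialect header + format-16 signal files
# ---------------------------------------------------------------------------


def write_record(record: EcgRecord, path, dialect: str = "synthetic",
                 gain: float = DEFAULT_GAIN) -> Path:
    """Write ``record`` as WFDB-dialect files rooted at ``path``.

    ``path`` is the record stem (no extension); ``<stem>.hea`` and
    ``<stem>.dat`` are produced.  Multiclass labels for the ``cinc2017``
    dialect go to a ``REFERENCE.csv`` sidecar in the same directory; the
    ``cinc2020`` and ``synthetic`` dialects embed labels as a ``# Dx:``
    comment.  Returns the header path.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    stem = Path(path)
    stem.parent.mkdir(parents=True, exist_ok=True)

    digitized = np.rint(record.signal * gain)
    if np.abs(digitized).max(initial=0.0) > 32767:
        raise ValueError("signal exceeds 16-bit range at this gain")
    digitized = digitized.astype("<i2")

    dat_name = stem.name + ".dat"
    lines = [f"{stem.name} {record.n_leads} {record.fs:g} {record.n_samples}"]
    for li, lead in enumerate(record.lead_names):
        init = int(digitized[li, 0]) if record.n_samples else 0
        lines.append(f"{dat_name} 16 {gain:g}/mV 16 0 {init} 0 0 {lead}")
    if record.age is not None:
        lines.append(f"# Age: {record.age}")
    if record.sex is not None:
        lines.append(f"# Sex: {record.sex.capitalize()}")
    lines.append(f"# Source: {record.source}")
    if dialect in ("cinc2020", "synthetic"):
        if record.labels:
            lines.append("# Dx: " + ",".join(sorted(record.labels)))
        else:
            warnings.warn(f"record {record.record_id} has no labels", stacklevel=2)
    (stem.parent / (stem.name + ".hea")).write_text("\n".join(lines) + "\n")

    # format 16: sample-interleaved little-endian int16
    digitized.T.tofile(stem.parent / dat_name)

    if dialect == "cinc2017":
        ref = stem.parent / "REFERENCE.csv"
        if not record.labels:
            warnings.warn(f"record {record.record_id} has no labels", stacklevel=2)
            label = ""
        else:
            (label,) = record.labels if len(record.labels) == 1 else (sorted(record.labels)[0],)
        rows: dict[str, str] = {}
        if ref.exists():
            with ref.open() as fh:
                rows = {r[0]: r[1] for r in csv.reader(fh) if r}
        rows[stem.name] = label
        with ref.open("w", newline="") as fh:
            w = csv.writer(fh)
            for k in sorted(rows):
                w.writerow([k, rows[k]])
    return stem.parent / (stem.name + ".hea")


def read_record(path, dialect: str = "synthetic",
                scheme: LabelScheme | None = None) -> EcgRecord:
    """Read a WFDB-dialect record written by :func:`write_record`.

    ``path`` may be the header file or the extension-less stem.  Signal values
    are converted to millivolts using the per-lead gain; demographics are
    parsed from header comment lines when present.  Ages masked at the HIPAA
    cap (92 for patients older than 89) are passed through unchanged.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    stem = Path(path)
    if stem.suffix == ".hea":
        stem = stem.with_suffix("")
    hea = stem.parent / (stem.name + ".hea")
    if not hea.exists():
        raise FileNotFoundError(f"header file not found: {hea}")

    header_lines = [ln.rstrip() for ln in hea.read_text().splitlines() if ln.strip()]
    first = header_lines[0].split()
    try:
        rec_id, n_leads, fs, n_samples = first[0], int(first[1]), float(first[2]), int(first[3])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"malformed header line in {hea}: {header_lines[0]!r}") from exc

    lead_specs = header_lines[1 : 1 + n_leads]
    if len(lead_specs) < n_leads:
        raise FormatError(f"{hea}: header declares {n_leads} leads but lists {len(lead_specs)}")
    gains, baselines, lead_names, dat_names = [], [], [], []
    for ln in lead_specs:
        parts = ln.split()
        dat_names.append(parts[0])
        gain_field = parts[2].split("/")[0]
        if "(" in gain_field:
            g, b = gain_field.split("(")
            baselines.append(float(b.rstrip(")")))
            gains.append(float(g))
        else:
            gains.append(float(gain_field))
            baselines.append(0.0)
        lead_names.append(parts[-1])

    age = sex = None
    source = "unknown"
    raw_codes: list[str] = []
    for ln in header_lines[1 + n_leads :]:
        if not ln.startswith("#"):
            continue
        body = ln.lstrip("#").strip()
        key, _, value = body.partition(":")
        key, value = key.strip().lower(), value.strip()
        if key == "age" and value and value.lower() not in ("nan", "unknown", "-"):
            age = int(round(float(value)))
        elif key == "sex" and value:
            v = value.lower()
            if v in ("male", "m"):
                sex = "male"
            elif v in ("female", "f"):
                sex = "female"
        elif key == "dx":
            raw_codes = [c for c in value.split(",") if c.strip()]
        elif key == "source":
            source = value

    dat = stem.parent / dat_names[0]
    if not dat.exists():
        raise FileNotFoundError(f"signal file not found: {dat}")
    raw = np.fromfile(dat, dtype="<i2")
    if raw.size != n_leads * n_samples:
        raise FormatError(
            f"{dat}: expected {n_leads}x{n_samples}={n_leads * n_samples} samples, "
            f"file holds {raw.size}"
        )
    mat = raw.reshape(n_samples, n_leads).T.astype(float)
    mat = (mat - np.asarray(baselines)[:, None]) / np.asarray(gains)[:, None]

    labels: set[str] = set()
    if dialect == "cinc2017":
        ref = stem.parent / "REFERENCE.csv"
        if ref.exists():
            with ref.open() as fh:
                for row in csv.reader(fh):
                    if row and row[0] == stem.name and len(row) > 1 and row[1]:
                        labels = {row[1]}
        if scheme is None:
            scheme = LabelScheme.cinc2017()
        labels = scheme.normalize(labels)
    else:
        labels = scheme.normalize(raw_codes) if scheme is not None else set(raw_codes)

    if source == "unknown" and dialect != "synthetic":
        source = dialect
    return EcgRecord(
        record_id=rec_id, signal=mat, fs=fs, lead_names=lead_names,
        labels=labels, age=age, sex=sex, source=source,
    )


def make_split(ids, ratios=(0.6, 0.2, 0.2), seed: int = 0,
               strata: dict[str, str] | None = None) -> DatasetSplit:
    """Randomly partition ``ids`` into train/validation/test.

    With ``strata`` (id -> label) given, the split is performed within each
    label group so per-class proportions are preserved to within one record.
    Deterministic for a fixed ``seed``.
    """
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("ids must be unique")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    rng = np.random.default_rng(seed)

    def _split_group(group: list[str]):
        order = [group[i] for i in rng.permutation(len(group))]
        n = len(order)
        n_train = int(round(ratios[0] * n))
        n_val = int(round(ratios[1] * n))
        n_val = min(n_val, n - n_train)
        return order[:n_train], order[n_train : n_train + n_val], order[n_train + n_val :]

    if strata is None:
        tr, va, te = _split_group(ids)
    else:
        tr, va, te = [], [], []
        by_label: dict[str, list[str]] = {}
        for i in ids:
            by_label.setdefault(str(strata[i]), []).append(i)
        for label in sorted(by_label):
            t, v, s = _split_group(by_label[label])
            tr += t
            va += v
            te += s
    return DatasetSplit(tr, va, te, seed)
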