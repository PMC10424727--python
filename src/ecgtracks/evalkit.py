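"""Evaluation: one-vs-rest metrics, k-fold cross-validation, per-source
breakdown and the efficiency (energy / CO2 / latency) harness.

Averaging is macro (unweighted over classes) by default — with heavy class
imbalance the rare classes would otherwise vanish from the headline number.
Zero-division convention, made explicit because rare classes hit it often:
a metric whose denominator is zero is 1 when the class produced no errors
(absent and never predicted) and 0 otherwise.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import LabelScheme


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvalReport:
    per_class: dict[str, dict[str, float]]
    averaged: dict[str, float]
    counts: dict[str, ConfusionCounts] = field(default_factory=dict)
    cv_mean: dict[str, float] | None = None
    cv_sd: dict[str, float] | None = None
    per_source: dict[str, dict[str, float]] | None = None

    def to_dict(self) -> dict:
        out = {"per_class": self.per_class, "averaged": self.averaged}
        if self.cv_mean is not None:
            out["cv_mean"] = self.cv_mean
            out["cv_sd"] = self.cv_sd
        if self.per_source is not None:
            out["per_source"] = self.per_source
        return out

    def markdown(self) -> str:
        lines = ["| class | F1 | SENS | SPEC |", "|---|---|---|---|"]
        for c, m in self.per_class.items():
            lines.append(f"| {c} | {m['f1']:.3f} | {m['sensitivity']:.3f} "
                         f"| {m['specificity']:.3f} |")
        a = self.averaged
        lines.append(f"| **macro** | {a['f1']:.3f} | {a['sensitivity']:.3f} "
                     f"| {a['specificity']:.3f} |")
        return "\n".join(lines)


@dataclass
class EfficiencyReport:
    """Per-record averages; energy is integrated over the whole run."""

    energy_wh: float
    co2_g: float
    time_processing_ms: float
    time_predicting_ms: float
    time_total_ms: float
    n_records: int
    estimated: bool = True  # True when energy comes from the TDP-share model

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _as_set(labels) -> frozenset:
    if isinstance(labels, (set, frozenset, list, tuple)):
        return frozenset(labels)
    return frozenset([labels])


def confusion_counts(truth, predicted, classes) -> dict[str, ConfusionCounts]:
    """One-vs-rest TP/FP/TN/FN per class."""
    if len(truth) != len(predicted):
        raise ValueError(f"length mismatch: {len(truth)} truth vs "
                         f"{len(predicted)} predicted")
    counts = {c: ConfusionCounts() for c in classes}
    for t, p in zip(truth, predicted):
        t, p = _as_set(t), _as_set(p)
        for c in classes:
            in_t, in_p = c in t, c in p
            cc = counts[c]
            if in_t and in_p:
                cc.tp += 1
            elif in_t:
                cc.fn += 1
            elif in_p:
                cc.fp += 1
            else:
                cc.tn += 1
    return counts


def _safe_div(num, den, errors) -> float:
    if den == 0:
        return 1.0 if errors == 0 else 0.0
    return num / den


def metrics_from_counts(cc: ConfusionCounts) -> dict[str, float]:
    errors = cc.fp + cc.fn
    precision = _safe_div(cc.tp, cc.tp + cc.fp, errors)
    recall = _safe_div(cc.tp, cc.tp + cc.fn, errors)
    specificity = _safe_div(cc.tn, cc.tn + cc.fp, errors)
    f1 = _safe_div(2 * precision * recall, precision + recall, errors)
    return {"precision": precision, "sensitivity": recall,
            "specificity": specificity, "f1": f1}


def compute_metrics(truth, predicted, scheme: LabelScheme,
                    average: str = "macro") -> EvalReport:
    """Per-class and averaged F1 / sensitivity / specificity.

    ``truth`` and ``predicted`` are aligned sequences of label sets (or bare
    labels).  ``average`` is ``macro`` (unweighted class mean, default) or
    ``micro`` (pooled counts).
    """
    counts = confusion_counts(truth, predicted, scheme.classes)
    per_class = {c: metrics_from_counts(cc) for c, cc in counts.items()}
    if average == "macro":
        averaged = {
            k: float(np.mean([m[k] for m in per_class.values()]))
            for k in ("precision", "sensitivity", "specificity", "f1")
        }
    elif average == "micro":
        pooled = ConfusionCounts(
            tp=sum(c.tp for c in counts.values()),
            fp=sum(c.fp for c in counts.values()),
            tn=sum(c.tn for c in counts.values()),
            fn=sum(c.fn for c in counts.values()),
        )
        averaged = metrics_from_counts(pooled)
    else:
        raise ValueError(f"unknown average {average!r}")
    return EvalReport(per_class=per_class, averaged=averaged, counts=counts)


def stratified_folds(labels_list, k: int, seed: int) -> list[np.ndarray]:
    """Disjoint covering validation folds, stratified by (first) label."""
    first = [sorted(_as_set(lb))[0] if _as_set(lb) else "" for lb in labels_list]
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    by_label: dict[str, list[int]] = {}
    for i, lb in enumerate(first):
        by_label.setdefault(lb, []).append(i)
    offset = 0
    for lb in sorted(by_label):
        idx = np.asarray(by_label[lb])
        idx = idx[rng.permutation(len(idx))]
        for j, i in enumerate(idx):
            folds[(j + offset) % k].append(int(i))
        offset += len(idx)
    return [np.asarray(sorted(f), dtype=int) for f in folds]


def crossvalidate(records, labels_list, fit_predict, scheme: LabelScheme,
                  k: int = 5, seed: int = 0) -> EvalReport:
    """k-fold cross-validation of an arbitrary fit/predict callable.

    ``fit_predict(train_records, train_labels, test_records)`` must return
    predicted label sets for the held-out fold.  Folds are stratified by
    first label; the report carries the mean and population SD (over folds)
    of each averaged metric.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(records) < k:
        raise ValueError("need at least k records")
    folds = stratified_folds(labels_list, k, seed)
    fold_reports = []
    for vi, val_idx in enumerate(folds):
        train_idx = np.asarray(sorted(set(range(len(records))) - set(val_idx)))
        tr_labels = [labels_list[i] for i in train_idx]
        present = set().union(*(_as_set(lb) for lb in tr_labels))
        missing = [c for c in scheme.classes if c not in present]
        if missing:
            warnings.warn(f"fold {vi}: classes {missing} absent from training",
                          stacklevel=2)
        preds = fit_predict([records[i] for i in train_idx], tr_labels,
                            [records[i] for i in val_idx])
        fold_reports.append(compute_metrics(
            [labels_list[i] for i in val_idx], preds, scheme))
    keys = ("precision", "sensitivity", "specificity", "f1")
    vals = {kk: np.array([r.averaged[kk] for r in fold_reports]) for kk in keys}
    report = EvalReport(
        per_class=fold_reports[0].per_class,  # illustrative first fold
        averaged={kk: float(vals[kk].mean()) for kk in keys},
        cv_mean={kk: float(vals[kk].mean()) for kk in keys},
        cv_sd={kk: float(vals[kk].std()) for kk in keys},  # population SD
    )
    return report


def per_source_report(records, truth, predicted, scheme: LabelScheme
                      ) -> dict[str, dict[str, float]]:
    """Macro-F1 and mean signal length per source tag."""
    by_source: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        by_source.setdefault(rec.source, []).append(i)
    table = {}
    for src in sorted(by_source):
        idx = by_source[src]
        rep = compute_metrics([truth[i] for i in idx],
                              [predicted[i] for i in idx], scheme)
        table[src] = {
            "f1": rep.averaged["f1"],
            "mean_length_s": float(np.mean([records[i].length_s for i in idx])),
            "n": len(idx),
        }
    return table


def profile(processing_fn, predicting_fn, records,
            carbon_intensity_g_per_wh: float = 0.4,
            cpu_tdp_w: float = 65.0, cpu_load_share: float = 1.0,
            ) -> EfficiencyReport:
    """Measure per-record processing and predicting wall time, and estimate
    energy with a TDP-share model.

    ``processing_fn(record) -> model input``; ``predicting_fn(input) ->
    scores``.  Energy is ``elapsed_seconds * cpu_tdp_w * cpu_load_share``
    converted to watt-hours (no hardware power counters are read, hence
    ``estimated=True``); CO2 grams are energy times the configurable grid
    carbon intensity (default 0.4 g/Wh, a typical mixed grid).
    """
    if not records:
        raise ValueError("no records to profile")
    t_proc = 0.0
    t_pred = 0.0
    for rec in records:
        t0 = time.perf_counter()
        x = processing_fn(rec)
        t1 = time.perf_counter()
        predicting_fn(x)
        t2 = time.perf_counter()
        t_proc += t1 - t0
        t_pred += t2 - t1
    n = len(records)
    energy_wh = (t_proc + t_pred) * cpu_tdp_w * cpu_load_share / 3600.0
    return EfficiencyReport(
        energy_wh=energy_wh,
        co2_g=energy_wh * carbon_intensity_g_per_wh,
        time_processing_ms=1000.0 * t_proc / n,
        time_predicting_ms=1000.0 * t_pred / n,
        time_total_ms=1000.0 * (t_proc + t_pred) / n,
        n_records=n,
    )
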