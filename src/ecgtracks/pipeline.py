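"""End-to-end run orchestration: data preparation, model optimisation and
performance/efficiency evaluation, with every artifact written to disk."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import evalkit, nets, synth, tsboost
from .io import DatasetSplit, LabelScheme, make_split

logger = logging.getLogger(__name__)

TRACKS = ("poincare", "raw1d", "features")


@dataclass
class RunConfig:
    """One experiment: one track, one model, one seed."""

    track: str
    model: str  # resnet1d | cnn1d | resnet50 | densenet121 | xgboost
    out_dir: str
    seed: int = 0
    # synthetic-data conditions
    class_mix: dict = field(default_factory=lambda: {
        "sinus": 30, "af": 10, "tachy": 10, "brady": 10})
    duration_s: float = 10.0
    fs: float = 300.0
    dialect: str = "cinc2017"
    # training
    epochs: int = 15
    width_scale: float = 0.25
    image_size: int = 32
    n_trials: int = 10
    carbon_intensity_g_per_wh: float = 0.4

    def validate(self) -> None:
        if self.track not in TRACKS:
            raise ValueError(f"track must be one of {TRACKS}")
        track_models = {
            "poincare": ("resnet50", "densenet121"),
            "raw1d": ("cnn1d", "resnet1d"),
            "features": ("xgboost",),
        }
        if self.model not in track_models[self.track]:
            raise ValueError(
                f"model {self.model!r} does not run on track {self.track!r}")

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute one configured run; returns the merged result summary.

    Artifacts written to ``config.out_dir``: ``split.json``,
    ``model_description.json`` (NN tracks), ``eval_report.json``,
    ``efficiency_report.json``, ``decisions.json`` (per-record test
    decisions) and ``summary.json``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.perf_counter()

    pairs = synth.simulate_dataset(config.class_mix, dialect=config.dialect,
                                   seed=config.seed,
                                   duration_s=config.duration_s)
    records = [rec for rec, _ in pairs]
    labels = {rec.record_id: sorted(rec.labels)[0] for rec in records}
    classes = sorted(config.class_mix)
    scheme = LabelScheme.synthetic(classes)

    split = make_split([r.record_id for r in records], seed=config.seed,
                       strata=labels)
    split.to_json(out / "split.json")
    by_id = {r.record_id: r for r in records}
    train_recs = [by_id[i] for i in split.train_ids]
    val_recs = [by_id[i] for i in split.val_ids]
    test_recs = [by_id[i] for i in split.test_ids]

    if config.track == "features":
        result, decided, report, eff = _run_features(
            config, scheme, train_recs, val_recs, test_recs, out)
    else:
        result, decided, report, eff = _run_net(
            config, scheme, train_recs, val_recs, test_recs, out)

    (out / "eval_report.json").write_text(json.dumps(report.to_dict(), indent=1))
    (out / "efficiency_report.json").write_text(json.dumps(eff.to_dict(), indent=1))
    (out / "decisions.json").write_text(json.dumps(
        {r.record_id: sorted(d) for r, d in zip(test_recs, decided)}, indent=1))
    summary = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "track": config.track,
        "model": config.model,
        "classes": classes,
        "test_macro_f1": report.averaged["f1"],
        "test_macro_sensitivity": report.averaged["sensitivity"],
        "test_macro_specificity": report.averaged["specificity"],
        "energy_wh": eff.energy_wh,
        "co2_g": eff.co2_g,
        "time_total_ms": eff.time_total_ms,
        "wall_time_s": time.perf_counter() - t_start,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def _run_net(config, scheme, train_recs, val_recs, test_recs, out):
    classes = scheme.classes
    n_classes = len(classes)
    if config.model in ("cnn1d", "resnet1d"):
        input_len = int(round(config.duration_s * config.fs)) - 1
        if config.model == "cnn1d":
            bundle = nets.build_cnn1d(n_classes, input_len=input_len,
                                      width_scale=config.width_scale,
                                      seed=config.seed)
        else:
            bundle = nets.build_resnet1d(n_classes,
                                         width_scale=config.width_scale,
                                         seed=config.seed)
        prep = dict(target_fs=config.fs, window_s=config.duration_s)
    else:
        bundle = nets.build_image2d(config.model, n_classes,
                                    image_size=config.image_size,
                                    width_scale=config.width_scale,
                                    depth_scale=config.width_scale,
                                    seed=config.seed)
        prep = {}
    bundle.classes = classes
    bundle.dump_description(out / "model_description.json")

    enc = lambda rs: nets.encode_labels(classes, [r.labels for r in rs],
                                        "multiclass")
    X_tr = nets.prepare_batch(bundle, train_recs, **prep)
    X_va = nets.prepare_batch(bundle, val_recs, **prep)
    tc = nets.TrainConfig(epochs=config.epochs, seed=config.seed)
    nets.train(bundle, (X_tr, enc(train_recs)), (X_va, enc(val_recs)), tc)
    bundle.save_weights(out / "weights.npz")

    X_te = nets.prepare_batch(bundle, test_recs, **prep)
    proba = nets.predict(bundle, X_te)
    decided = nets.decide(bundle, proba)
    truth = [r.labels for r in test_recs]
    report = evalkit.compute_metrics(truth, decided, scheme)
    report.per_source = evalkit.per_source_report(test_recs, truth, decided,
                                                 scheme)
    eff = evalkit.profile(
        lambda rec: nets.prepare_input(bundle, rec, **prep),
        lambda x: nets.predict(bundle, x[None]),
        test_recs,
        carbon_intensity_g_per_wh=config.carbon_intensity_g_per_wh)
    return bundle, decided, report, eff


def _run_features(config, scheme, train_recs, val_recs, test_recs, out):
    trainval = train_recs + val_recs
    table_tr = tsboost.extract_features(trainval)
    table_tr, retained = tsboost.impute_and_filter(table_tr)
    labels_tr = [sorted(r.labels)[0] for r in trainval]
    result = tsboost.tune_and_fit(table_tr, labels_tr,
                                  n_trials=config.n_trials, seed=config.seed)
    (out / "best_config.json").write_text(json.dumps(
        {"params": result.best_params, "score": result.best_score,
         "n_selected": len(result.selected_features)}, indent=1))
    with (out / "trials.jsonl").open("w") as fh:
        for t in result.trials:
            fh.write(json.dumps(t) + "\n")
    table_te, _ = tsboost.impute_and_filter(
        tsboost.extract_features(test_recs), retained=retained)
    pred = tsboost.predict(result, table_te)
    decided = [{p} for p in pred]
    truth = [r.labels for r in test_recs]
    report = evalkit.compute_metrics(truth, decided, scheme)
    report.per_source = evalkit.per_source_report(test_recs, truth, decided,
                                                 scheme)
    try:
        imp = tsboost.feature_importance(result)
    except ValueError:
        # heavily-pruned boosters can end with zero recorded splits
        import pandas as pd

        imp = pd.DataFrame(columns=["n_features", "importance"])
        imp.index.name = "group"
    imp.to_csv(out / "feature_importance.csv")

    def _process(rec):
        t, _ = tsboost.impute_and_filter(
            tsboost.extract_features([rec]), retained=retained)
        return t

    eff = evalkit.profile(
        _process, lambda t: tsboost.predict(result, t), test_recs,
        carbon_intensity_g_per_wh=config.carbon_intensity_g_per_wh)
    return result, decided, report, eff


def report_runs(run_dirs, out_path=None, plot_path=None):
    """Merge run summaries into a comparison table sorted by test F1; refuse
    to merge runs evaluated on different label schemes."""
    rows = []
    for d in run_dirs:
        summary = json.loads((Path(d) / "summary.json").read_text())
        rows.append(summary)
    if not rows:
        raise ValueError("no completed runs given")
    schemes = {tuple(r["classes"]) for r in rows}
    if len(schemes) > 1:
        raise ValueError(f"incompatible label schemes across runs: {schemes}")
    rows.sort(key=lambda r: r["test_macro_f1"], reverse=True)
    table = [{k: r[k] for k in ("track", "model", "test_macro_f1",
                                "test_macro_sensitivity",
                                "test_macro_specificity", "energy_wh",
                                "co2_g", "time_total_ms")} for r in rows]
    if out_path:
        Path(out_path).write_text(json.dumps(table, indent=1))
    if plot_path:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for r in table:
            ax.scatter(r["co2_g"], r["test_macro_f1"])
            ax.annotate(r["model"], (r["co2_g"], r["test_macro_f1"]),
                        fontsize=8)
        ax.set_xlabel("CO$_2$ (g)")
        ax.set_ylabel("Test F1 score")
        fig.tight_layout()
        fig.savefig(plot_path)
        plt.close(fig)
    return table
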