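"""Desk-scale benchmark experiments exercising every track end to end.

Each function regenerates its inputs from a seed, runs the relevant part of
the package and returns measured quantities.  The synthetic study conditions
(sample sizes, noise levels, rhythm parameters) are fixed here; model
capacity is reduced via ``width_scale`` so the experiments fit a single CPU,
with the layouts untouched.
"""

from __future__ import annotations

import json
import tempfile
from pathlib import Path

import numpy as np

from . import evalkit, interpret, nets, poincare, preprocess, synth, tsboost
from .io import LabelScheme
from .pipeline import RunConfig, run_pipeline

FOUR_CLASSES = ("sinus", "af", "tachy", "brady")


# -- R-peak detector --------------------------------------------------------

def detector_benchmark(seed: int = 0, n_records: int = 50,
                       tolerance_s: float = 0.05) -> dict:
    """Beat-level sensitivity and PPV of the Hamilton detector against
    ground truth on a mixed-rhythm synthetic suite."""
    mix = {"sinus": 14, "af": 12, "tachy": 12, "brady": 12}
    scale = n_records / sum(mix.values())
    mix = {k: max(1, int(round(v * scale))) for k, v in mix.items()}
    pairs = synth.simulate_dataset(mix, dialect="cinc2017", seed=seed,
                                   duration_s=30.0)
    tp = fn = fp = 0
    for rec, gt in pairs:
        beats = preprocess.detect_rpeaks(rec.signal[0], rec.fs)
        det_t = beats.r_peaks / rec.fs
        for t in gt.r_peak_times:
            if det_t.size and np.abs(det_t - t).min() <= tolerance_s:
                tp += 1
            else:
                fn += 1
        for d in det_t:
            if np.abs(gt.r_peak_times - d).min() > tolerance_s:
                fp += 1
    return {"sensitivity": tp / (tp + fn), "ppv": tp / (tp + fp),
            "n_records": len(pairs), "n_beats": tp + fn}


# -- Poincare oracle --------------------------------------------------------

def poincare_oracle(seed: int = 0, n_series: int = 1000) -> dict:
    """build_points vs brute-force pairing; transpose symmetry of
    rasterization; point-count conservation."""
    rng = np.random.default_rng(seed)
    matches = 0
    for _ in range(n_series):
        nn_ivals = rng.uniform(0.3, 2.0, size=rng.integers(2, 120))
        pts = poincare.build_points(nn_ivals).points
        brute = np.array([(nn_ivals[k], nn_ivals[k + 1])
                          for k in range(len(nn_ivals) - 1)])
        matches += int(np.array_equal(pts, brute))
    sym_ok = 0
    n_sym = 100
    for _ in range(n_sym):
        nn_ivals = rng.uniform(0.3, 1.5, size=30)
        a = poincare.rasterize(poincare.build_points(nn_ivals), size=96).pixels
        b = poincare.rasterize(poincare.build_points(nn_ivals[::-1]),
                               size=96).pixels
        sym_ok += int(np.array_equal(a, b.T))
    from scipy import ndimage

    well_sep = np.array([0.3, 1.5, 0.5, 1.2, 0.8])
    img = poincare.rasterize(poincare.build_points(well_sep), size=224)
    _, n_comp = ndimage.label(img.pixels > 0)
    return {"pairing_match_fraction": matches / n_series,
            "transpose_symmetry_fraction": sym_ok / n_sym,
            "component_count": int(n_comp), "expected_components": 4,
            "n_series": n_series}


# -- architecture audits ----------------------------------------------------

def architecture_audit() -> dict:
    cnn = nets.build_cnn1d(4, input_len=8999).describe()["root"]
    blocks = [l for l in cnn["layers"] if l["name"].startswith("block")]
    kernels = [b["layers"][0]["kernel"] for b in blocks]
    res = nets.build_resnet1d(4).describe()["root"]
    stem = res["layers"][0]["layers"][0]
    rblocks = [l for l in res["layers"] if l["type"] == "ResBlock1d"]
    head = res["layers"][-1]["layers"]
    return {
        "cnn1d_block_count": len(blocks),
        "cnn1d_kernel_schedule_ok": int(kernels == [20] + [5] * 5 + [3] * 6),
        "resnet1d_stem_kernel": stem["kernel"],
        "resnet1d_stem_channels": stem["out_channels"],
        "resnet1d_block_count": len(rblocks),
        "resnet1d_dual_pool_head_ok": int(
            head[0]["type"] == "DualPoolConcat1d"
            and head[0]["pools"] == ["avg", "max"]
            and head[1]["in_features"] == 2 * rblocks[-1]["channels"]),
    }


# -- metric oracle ----------------------------------------------------------

def _brute_force_metrics(truth, predicted, classes):
    per = {}
    for c in classes:
        tp = fp = tn = fn = 0
        for t, p in zip(truth, predicted):
            if c in t and c in p:
                tp += 1
            elif c in t:
                fn += 1
            elif c in p:
                fp += 1
            else:
                tn += 1
        prec = tp / (tp + fp) if tp + fp else (1.0 if fn == 0 else 0.0)
        rec = tp / (tp + fn) if tp + fn else (1.0 if fp == 0 else 0.0)
        f1 = (2 * prec * rec / (prec + rec) if prec + rec
              else (1.0 if fp + fn == 0 else 0.0))
        spec = tn / (tn + fp) if tn + fp else (1.0 if fp + fn == 0 else 0.0)
        per[c] = (prec, rec, spec, f1)
    return per


def metric_oracle(seed: int = 0, n_instances: int = 1000) -> dict:
    """compute_metrics vs an independent enumeration, multiclass and
    multilabel, plus the closed-form TP=FP=FN=1 case."""
    rng = np.random.default_rng(seed)
    classes = ["a", "b", "c", "d"]
    scheme = LabelScheme.synthetic(classes)
    mscheme = LabelScheme.synthetic_multilabel(classes)
    max_dev = 0.0
    for i in range(n_instances):
        n = int(rng.integers(5, 40))
        if i % 2 == 0:
            truth = [{classes[j]} for j in rng.integers(0, 4, n)]
            pred = [{classes[j]} for j in rng.integers(0, 4, n)]
            rep = evalkit.compute_metrics(truth, pred, scheme)
        else:
            truth = [set(np.array(classes)[rng.random(4) < 0.4]) or {"a"}
                     for _ in range(n)]
            pred = [set(np.array(classes)[rng.random(4) < 0.4]) or {"b"}
                    for _ in range(n)]
            rep = evalkit.compute_metrics(truth, pred, mscheme)
        brute = _brute_force_metrics(truth, pred, classes)
        for c in classes:
            got = rep.per_class[c]
            exp = brute[c]
            max_dev = max(
                max_dev,
                abs(got["precision"] - exp[0]), abs(got["sensitivity"] - exp[1]),
                abs(got["specificity"] - exp[2]), abs(got["f1"] - exp[3]))
    # closed-form case: one TP, one FP, one FN for class 'a'
    rep = evalkit.compute_metrics([{"a"}, {"a"}, {"b"}], [{"a"}, {"b"}, {"a"}],
                                  scheme)
    f1_case = rep.per_class["a"]["f1"]
    return {"max_abs_deviation": max_dev, "formula_case_f1": f1_case,
            "n_instances": n_instances}


# -- classifier recovery ----------------------------------------------------

def _four_class_raw_dataset(seed: int, per_class: int = 250,
                            duration_s: float = 10.0):
    mix = {k: per_class for k in FOUR_CLASSES}
    pairs = synth.simulate_dataset(mix, dialect="cinc2017", seed=seed,
                                   duration_s=duration_s)
    recs = [r for r, _ in pairs]
    classes = sorted(FOUR_CLASSES)
    y = nets.encode_labels(classes, [r.labels for r in recs], "multiclass")
    return recs, y, classes


def resnet1d_recovery(seed: int = 0, width_scale: float = 0.25,
                      epochs: int = 30, with_null: bool = True) -> dict:
    """1D ResNet on the separable 4-class raw-signal task: 600/200/200
    records of 10 s at 300 Hz, plus a label-permutation null control."""
    recs, y, classes = _four_class_raw_dataset(seed)
    bundle = nets.build_resnet1d(4, width_scale=width_scale, seed=seed)
    bundle.classes = classes
    X = nets.prepare_batch(bundle, recs, target_fs=300.0, window_s=10.0)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(X))
    tr, va, te = order[:600], order[600:800], order[800:]
    cfg = nets.TrainConfig(epochs=epochs, seed=seed, patience=12)
    nets.train(bundle, (X[tr], y[tr]), (X[va], y[va]), cfg)
    proba = nets.predict(bundle, X[te])
    truth = [{classes[i]} for i in y[te]]
    rep = evalkit.compute_metrics(truth, nets.decide(bundle, proba),
                                  LabelScheme.synthetic(classes))
    out = {"test_macro_f1": rep.averaged["f1"],
           "epochs_run": len(bundle.history),
           "n_train": len(tr), "n_test": len(te)}
    if with_null:
        y_null = y.copy()
        y_null[tr] = np.random.default_rng(seed + 1).permutation(y[tr])
        null_bundle = nets.build_resnet1d(4, width_scale=width_scale,
                                          seed=seed)
        null_bundle.classes = classes
        nets.train(null_bundle, (X[tr], y_null[tr]), (X[va], y[va]),
                   nets.TrainConfig(epochs=10, seed=seed, patience=10,
                                    min_epochs=10))
        proba_n = nets.predict(null_bundle, X[te])
        rep_n = evalkit.compute_metrics(
            truth, nets.decide(null_bundle, proba_n),
            LabelScheme.synthetic(classes))
        out["null_test_macro_f1"] = rep_n.averaged["f1"]
    return out


def cnn1d_recovery(seed: int = 0, width_scale: float = 0.25,
                   epochs: int = 20) -> dict:
    """12-block CNN on a two-class morphology task (clean sinus vs heavily
    noise-corrupted rhythm) at the 30 s records its receptive field needs.

    An all-max-pooling stack is a poor rate counter but a strong local
    texture detector, so the control contrasts signal texture, not rate.
    """
    mix = {"sinus": 60, "noisy": 60}
    pairs = synth.simulate_dataset(mix, dialect="cinc2017", seed=seed,
                                   duration_s=30.0)
    recs = [r for r, _ in pairs]
    classes = ["noisy", "sinus"]
    y = nets.encode_labels(classes, [r.labels for r in recs], "multiclass")
    bundle = nets.build_cnn1d(2, input_len=8999, width_scale=width_scale,
                              seed=seed)
    bundle.classes = classes
    X = nets.prepare_batch(bundle, recs, target_fs=300.0, window_s=30.0)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(X))
    tr, va, te = order[:72], order[72:96], order[96:]
    cfg = nets.TrainConfig(epochs=epochs, seed=seed, patience=epochs,
                           batch_size=16, lr=1e-2)
    nets.train(bundle, (X[tr], y[tr]), (X[va], y[va]), cfg)
    proba = nets.predict(bundle, X[te])
    truth = [{classes[i]} for i in y[te]]
    rep = evalkit.compute_metrics(truth, nets.decide(bundle, proba),
                                  LabelScheme.synthetic(classes))
    return {"test_macro_f1": rep.averaged["f1"], "n_test": len(te)}


def poincare_recovery(seed: int = 0, image_size: int = 32,
                      scale: float = 0.25, epochs: int = 12) -> dict:
    """DenseNet on rasterized Poincare diagrams, AF vs sinus (same mean RR;
    the cloud shape is the only cue), 200 held-out diagrams."""
    mix = {"af": 350, "sinus": 350}
    pairs = synth.simulate_dataset(mix, dialect="cinc2017", seed=seed,
                                   duration_s=30.0)
    recs = [r for r, _ in pairs]
    classes = ["af", "sinus"]
    bundle = nets.build_image2d("densenet121", 2, image_size=image_size,
                                width_scale=scale, depth_scale=scale,
                                seed=seed)
    bundle.classes = classes
    X = nets.prepare_batch(bundle, recs)
    y = nets.encode_labels(classes, [r.labels for r in recs], "multiclass")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(X))
    tr, va, te = order[:400], order[400:500], order[500:700]
    cfg = nets.TrainConfig(epochs=epochs, seed=seed, patience=epochs)
    nets.train(bundle, (X[tr], y[tr]), (X[va], y[va]), cfg)
    proba = nets.predict(bundle, X[te])
    truth = [{classes[i]} for i in y[te]]
    rep = evalkit.compute_metrics(truth, nets.decide(bundle, proba),
                                  LabelScheme.synthetic(classes))
    return {"test_macro_f1": rep.averaged["f1"], "n_test": len(te)}


# -- boosting track ---------------------------------------------------------

def boosting_benchmark(seed: int = 0, per_class: int = 75,
                       n_trials: int = 12) -> dict:
    """Tuned XGBoost on the 4-class synthetic feature table; also verifies
    the imputation constant and that every sampled configuration respects
    the search-space bounds."""
    mix = {k: per_class for k in FOUR_CLASSES}
    pairs = synth.simulate_dataset(mix, dialect="cinc2017", seed=seed,
                                   duration_s=10.0)
    recs = [r for r, _ in pairs]
    labels = [sorted(r.labels)[0] for r in recs]
    table = tsboost.extract_features(recs)
    # plant one missing value to observe the imputation constant directly
    probe_col = table.columns[0]
    table.iloc[0, 0] = np.nan
    filled, _ = tsboost.impute_and_filter(table.iloc[:1],
                                          retained=[probe_col])
    fill_observed = float(filled.iloc[0, 0])
    table.iloc[0, 0] = 0.0

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(recs))
    n_tr = int(0.8 * len(recs))
    tr, te = order[:n_tr], order[n_tr:]
    tab_tr, retained = tsboost.impute_and_filter(table.iloc[tr])
    tab_te, _ = tsboost.impute_and_filter(table.iloc[te], retained=retained)
    res = tsboost.tune_and_fit(tab_tr, [labels[i] for i in tr],
                               n_trials=n_trials, seed=seed)
    space = tsboost.SearchSpace.default(tab_tr.shape[1])
    in_bounds = all(
        lo <= t["params"][name] <= hi
        for t in res.trials for name, (lo, hi, _) in space.dims.items())
    pred = tsboost.predict(res, tab_te)
    scheme = LabelScheme.synthetic(sorted(FOUR_CLASSES))
    rep = evalkit.compute_metrics([{labels[i]} for i in te],
                                  [{p} for p in pred], scheme)
    return {"test_macro_f1": rep.averaged["f1"],
            "n_trials": len(res.trials),
            "all_params_in_bounds": int(in_bounds),
            "imputation_fill_value": fill_observed,
            "n_features": tab_tr.shape[1]}


# -- GradCAM localization ---------------------------------------------------

def gradcam_localization(seed: int = 0, n_records: int = 300,
                         length: int = 1500, window: int = 300,
                         epochs: int = 10) -> dict:
    """Planted-pattern control: class 1 carries a sinusoidal burst in a
    known window; saliency mass inside the window is measured on correctly
    classified positives.  Also checks the zero-gradient null map."""
    rng = np.random.default_rng(seed)
    X = (rng.standard_normal((n_records, 1, length)) * 0.3).astype(np.float32)
    y = np.zeros(n_records, dtype=int)
    wins = []
    t = np.arange(window)
    burst = np.sin(2 * np.pi * t / 12.0).astype(np.float32)
    for i in range(n_records):
        if i % 2 == 0:
            y[i] = 1
            s = int(rng.integers(0, length - window))
            X[i, 0, s : s + window] += burst
            wins.append((s, s + window))
        else:
            wins.append(None)
    bundle = nets.build_resnet1d(2, width_scale=0.125, seed=seed)
    bundle.classes = ["none", "pattern"]
    order = rng.permutation(n_records)
    tr, te = order[: int(0.75 * n_records)], order[int(0.75 * n_records) :]
    nets.train(bundle, (X[tr], y[tr]), (X[te], y[te]),
               nets.TrainConfig(epochs=epochs, seed=seed, patience=epochs))
    proba = nets.predict(bundle, X[te])
    pred = proba.argmax(axis=1)
    fracs = []
    for j, i in enumerate(te):
        if y[i] == 1 and pred[j] == 1:
            sal = interpret.gradcam(bundle, X[i], 1)
            fracs.append(interpret.saliency_mass_fraction(sal, wins[i]))
    zero_sal = interpret.gradcam(bundle, np.zeros((1, length),
                                                  dtype=np.float32), 1,
                                 layer=bundle.config["last_conv"])
    # zero-gradient null: sever the class score from the feature maps
    fc = bundle.net.root.named_modules()["head.fc"]
    saved = fc.w.value.copy()
    fc.w.value[...] = 0.0
    null_sal = interpret.gradcam(bundle, X[te[0]], 1)
    fc.w.value[...] = saved
    return {"mean_mass_fraction": float(np.mean(fracs)),
            "n_correct_positives": len(fracs),
            "null_heatmap_max": float(null_sal.heatmap.max()),
            "zero_input_heatmap_max": float(zero_sal.heatmap.max())}


# -- pipeline determinism ---------------------------------------------------

def pipeline_determinism(seed: int = 0, workdir: str | None = None) -> dict:
    """Two full synthetic runs with identical config and seed must produce
    identical split manifests and identical test decisions."""
    mix = {"sinus": 8, "af": 8, "tachy": 7, "brady": 7}
    ctx = (tempfile.TemporaryDirectory() if workdir is None else None)
    base = Path(ctx.name if ctx else workdir)
    outs = []
    try:
        for tag in ("run_a", "run_b"):
            cfg = RunConfig(track="raw1d", model="resnet1d",
                            out_dir=str(base / tag), seed=seed,
                            class_mix=mix, duration_s=10.0, epochs=2,
                            width_scale=0.0625)
            run_pipeline(cfg)
            outs.append(base / tag)
        split_same = (json.loads((outs[0] / "split.json").read_text())
                      == json.loads((outs[1] / "split.json").read_text()))
        dec_same = (json.loads((outs[0] / "decisions.json").read_text())
                    == json.loads((outs[1] / "decisions.json").read_text()))
    finally:
        if ctx:
            ctx.cleanup()
    return {"split_manifests_identical": int(split_same),
            "test_decisions_identical": int(dec_same)}
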