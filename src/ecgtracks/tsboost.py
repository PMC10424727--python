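"""The gradient-boosting track: feature extraction, imputation and variance
filtering, Bayesian hyperparameter search with embedded feature elimination,
and grouped split-frequency importance.

The search space is: ``min_features_to_select`` in [10, n_features] and
``max_depth`` in [2, 100], both uniform; ``gamma``, ``eta``,
``scale_pos_weight``, ``reg_lambda`` and ``reg_alpha`` log-uniform over
[1e-3, 1e3].  The optimiser is Gaussian-process expected improvement over
the unit hypercube, with the validation macro-F1 as objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from xgboost import XGBClassifier

from .features import EXCLUDED_FAMILIES, extract_feature_vector
from .io import EcgRecord

FILL_VALUE = -999.0


@dataclass
class SearchSpace:
    """Hyperparameter ranges: name -> (low, high, prior)."""

    dims: dict[str, tuple[float, float, str]]

    def __post_init__(self) -> None:
        for name, (lo, hi, prior) in self.dims.items():
            if prior not in ("uniform", "log-uniform"):
                raise ValueError(f"{name}: unknown prior {prior!r}")
            if prior == "log-uniform" and lo <= 0:
                raise ValueError(f"{name}: log-uniform bounds must be positive")
            if lo >= hi:
                raise ValueError(f"{name}: low must be below high")

    @classmethod
    def default(cls, n_features: int) -> "SearchSpace":
        return cls(dims={
            "min_features_to_select": (10, n_features, "uniform"),
            "max_depth": (2, 100, "uniform"),
            "gamma": (1e-3, 1e3, "log-uniform"),
            "eta": (1e-3, 1e3, "log-uniform"),
            "scale_pos_weight": (1e-3, 1e3, "log-uniform"),
            "reg_lambda": (1e-3, 1e3, "log-uniform"),
            "reg_alpha": (1e-3, 1e3, "log-uniform"),
        })

    def decode(self, u: np.ndarray) -> dict[str, float]:
        """Map a unit-hypercube point to hyperparameter values."""
        out = {}
        for ui, (name, (lo, hi, prior)) in zip(u, self.dims.items()):
            if prior == "uniform":
                v = lo + ui * (hi - lo)
            else:
                v = float(np.exp(np.log(lo) + ui * (np.log(hi) - np.log(lo))))
            if name in ("min_features_to_select", "max_depth"):
                v = int(round(v))
            out[name] = v
        return out


@dataclass
class BoostResult:
    model: XGBClassifier
    classes: list[str]
    selected_features: list[str]
    best_params: dict
    best_score: float
    trials: list[dict] = field(default_factory=list)


def extract_features(records: list[EcgRecord], lead: int = 0,
                     max_samples: int | None = None) -> pd.DataFrame:
    """One feature row per record, computed on a single configured lead.

    ``max_samples`` optionally truncates very long records before feature
    computation (the quadratic-free catalogue is fast, but truncation keeps
    the desk-scale pipeline predictable).  Column names never contain the
    excluded expensive families.
    """
    if not records:
        raise ValueError("no records given")
    rows = {}
    for rec in records:
        x = rec.signal[lead]
        if max_samples is not None:
            x = x[:max_samples]
        rows[rec.record_id] = extract_feature_vector(x)
    table = pd.DataFrame.from_dict(rows, orient="index")
    bad = [c for c in table.columns
           if any(f in c for f in EXCLUDED_FAMILIES)]
    assert not bad, f"excluded feature families leaked into the table: {bad}"
    return table


def impute_and_filter(table: pd.DataFrame, fill: float = FILL_VALUE,
                      var_threshold: float = 0.0,
                      train_index=None,
                      retained: list[str] | None = None,
                      ) -> tuple[pd.DataFrame, list[str]]:
    """Fill missing values with ``fill`` and drop low-variance columns.

    Variance is computed on the training rows only (``train_index``, default
    all rows); the retained-column list is returned so it can be re-applied
    verbatim to validation/test tables (pass it back as ``retained``).
    """
    table = table.replace([np.inf, -np.inf], np.nan).fillna(fill)
    if retained is None:
        fit_rows = table if train_index is None else table.loc[train_index]
        variances = fit_rows.var(axis=0, ddof=0)
        retained = [c for c in table.columns if variances[c] > var_threshold]
        if not retained:
            raise ValueError(
                f"variance threshold {var_threshold} removed every column")
    return table[retained], list(retained)


def _expected_improvement(gp, X_cand, best):
    mu, sd = gp.predict(X_cand, return_std=True)
    sd = np.maximum(sd, 1e-9)
    z = (mu - best) / sd
    return (mu - best) * sstats.norm.cdf(z) + sd * sstats.norm.pdf(z)


def _fit_xgb(params: dict, X, y, n_classes: int, seed: int,
             n_estimators: int) -> XGBClassifier:
    model = XGBClassifier(
        n_estimators=n_estimators,
        max_depth=int(params["max_depth"]),
        gamma=params["gamma"],
        learning_rate=params["eta"],
        scale_pos_weight=params["scale_pos_weight"],
        reg_lambda=params["reg_lambda"],
        reg_alpha=params["reg_alpha"],
        objective="multi:softprob" if n_classes > 2 else "binary:logistic",
        random_state=seed,
        n_jobs=1,
        verbosity=0,
    )
    model.fit(X, y)
    return model


def _rank_features(model: XGBClassifier, columns) -> list[str]:
    score = model.get_booster().get_score(importance_type="weight")
    return sorted(columns, key=lambda c: score.get(c, 0.0), reverse=True)


def _macro_f1(y_true, y_pred, n_classes) -> float:
    f1s = []
    for c in range(n_classes):
        tp = np.sum((y_pred == c) & (y_true == c))
        fp = np.sum((y_pred == c) & (y_true != c))
        fn = np.sum((y_pred != c) & (y_true == c))
        f1s.append(2 * tp / (2 * tp + fp + fn) if tp + fp + fn else 1.0)
    return float(np.mean(f1s))


def tune_and_fit(table: pd.DataFrame, labels: list[str],
                 space: SearchSpace | None = None, n_trials: int = 100,
                 seed: int = 0, val_fraction: float = 0.25,
                 n_estimators: int = 50) -> BoostResult:
    """Bayesian-optimised XGBoost with embedded feature elimination.

    Each trial samples a configuration, fits on the training rows, ranks
    features by split frequency, keeps the top ``min_features_to_select``,
    refits on the reduced set and scores validation macro-F1.  At most
    ``n_trials`` configurations are evaluated; the best model (refitted) is
    returned with its trial log.  Deterministic for a fixed seed.
    """
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to fit a classifier")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    space = space or SearchSpace.default(table.shape[1])
    rng = np.random.default_rng(seed)
    y = np.array([classes.index(lb) for lb in labels])

    # stratified train/val split of the rows
    val_idx = []
    for c in range(len(classes)):
        idx = np.flatnonzero(y == c)
        idx = idx[rng.permutation(idx.size)]
        val_idx.extend(idx[: max(1, int(round(val_fraction * idx.size)))])
    val_mask = np.zeros(len(y), dtype=bool)
    val_mask[val_idx] = True
    X_tr, y_tr = table.iloc[~val_mask], y[~val_mask]
    X_va, y_va = table.iloc[val_mask], y[val_mask]

    d = len(space.dims)
    n_init = min(max(4, d + 1), n_trials)
    trials: list[dict] = []
    observed_u: list[np.ndarray] = []
    observed_y: list[float] = []

    def evaluate(u: np.ndarray) -> float:
        params = space.decode(u)
        m = min(int(params["min_features_to_select"]), table.shape[1])
        model = _fit_xgb(params, X_tr, y_tr, len(classes), seed, n_estimators)
        keep = _rank_features(model, table.columns)[:m]
        model = _fit_xgb(params, X_tr[keep], y_tr, len(classes), seed,
                         n_estimators)
        score = _macro_f1(y_va, model.predict(X_va[keep]), len(classes))
        trials.append({"params": params, "score": score,
                       "n_features": len(keep)})
        observed_u.append(u)
        observed_y.append(score)
        return score

    for _ in range(n_init):
        evaluate(rng.random(d))
    while len(trials) < n_trials:
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5, length_scale=np.full(d, 0.3)),
            normalize_y=True, alpha=1e-4,
            random_state=int(rng.integers(2**31 - 1)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(np.vstack(observed_u), np.asarray(observed_y))
            cand = rng.random((256, d))
            ei = _expected_improvement(gp, cand, max(observed_y))
        evaluate(cand[int(np.argmax(ei))])

    best_i = int(np.argmax(observed_y))
    best = trials[best_i]
    params = best["params"]
    m = min(int(params["min_features_to_select"]), table.shape[1])
    model = _fit_xgb(params, X_tr, y_tr, len(classes), seed, n_estimators)
    keep = _rank_features(model, table.columns)[:m]
    model = _fit_xgb(params, X_tr[keep], y_tr, len(classes), seed,
                     n_estimators)
    return BoostResult(model=model, classes=classes, selected_features=keep,
                       best_params=params, best_score=best["score"],
                       trials=trials)


def predict(result: BoostResult, table: pd.DataFrame) -> list[str]:
    pred = result.model.predict(table[result.selected_features])
    return [result.classes[i] for i in pred]


def feature_importance(result: BoostResult, group_by_prefix: bool = True
                       ) -> pd.DataFrame:
    """Split-frequency importance, normalised to sum 1 and aggregated into
    groups (the column-name prefix before the ``__`` parameter suffix)."""
    booster = result.model.get_booster()
    score = booster.get_score(importance_type="weight")
    if not score:
        raise ValueError("model has no recorded splits; is it fitted?")
    total = sum(score.values())
    rows: dict[str, dict] = {}
    for feat in result.selected_features:
        key = feat.split("__")[0] if group_by_prefix else feat
        row = rows.setdefault(key, {"n_features": 0, "importance": 0.0})
        row["n_features"] += 1
        row["importance"] += score.get(feat, 0.0) / total
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "group"
    return df.sort_values("importance", ascending=False)
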