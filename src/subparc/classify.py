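"""Single-subject random-forest biomarker evaluation.

Class-balanced random forests, stratified 80/20 hold-out, stratified 5-fold
cross-validated hyperparameter search (TPE-style adaptive sampler with a
pure-random fallback), ROC/AUC on the untouched test set, F1-optimal
thresholding, bootstrap stability over training resamples, and normalised
impurity feature importances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from subparc.errors import ConfigError, StatsPreconditionError

__all__ = [
    "ClassifierSpec",
    "ClassifierReport",
    "stratified_split",
    "tune",
    "fit_and_test",
    "roc_curve_points",
    "auc_trapezoid",
    "f1_threshold",
    "confusion_report",
    "bootstrap_stability",
    "importance_ranking",
    "run_classifier",
]

DEFAULT_SPACE: dict[str, tuple] = {
    "n_estimators": ("int", 100, 1000),
    "max_depth": ("cat", (2, 5, 10, 20, None)),
    "min_samples_split": ("int", 2, 10),
    "max_features": ("cat", ("sqrt", "log2", 1.0)),
}


@dataclass
class ClassifierSpec:
    feature_columns: list[str]
    positive_class: str
    test_fraction: float = 0.20
    cv_folds: int = 5
    n_trials: int = 100
    n_boot: int = 200
    seed: int = 0
    space: dict = field(default_factory=lambda: dict(DEFAULT_SPACE))
    sampler: str = "tpe"  # or "random"

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigError("test_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        if self.n_trials < 1:
            raise ConfigError("n_trials must be >= 1")


@dataclass
class ClassifierReport:
    cv_aucs: list[float]
    cv_auc_mean: float
    best_params: dict
    trial_aucs: list[float]
    test_auc: float | None
    roc_fpr: list[float]
    roc_tpr: list[float]
    threshold_default: float
    threshold_f1: float
    confusion: dict  # tp/fp/tn/fn at the F1 threshold
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    bootstrap: dict | None = None
    importances: list[tuple[str, float]] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# splitting

def stratified_split(
    labels: np.ndarray, test_fraction: float = 0.20, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Group-stratified hold-out split.

    The total test size is ceil(test_fraction * n); per-class allocations
    use largest-remainder rounding, preserving class proportions. Returns
    (train indices, test indices), disjoint and exhaustive.
    """
    labels = np.asarray(labels)
    n = len(labels)
    n_test = int(np.ceil(test_fraction * n))
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 2):
        raise StatsPreconditionError("every class needs at least 2 members")
    quotas = counts * n_test / n
    alloc = np.floor(quotas).astype(int)
    remainder = quotas - alloc
    short = n_test - alloc.sum()
    for i in np.argsort(-remainder)[:short]:
        alloc[i] += 1
    rng = np.random.default_rng(seed)
    test_idx = []
    for cls, k in zip(classes, alloc):
        members = np.flatnonzero(labels == cls)
        test_idx.append(rng.choice(members, size=k, replace=False))
    test_idx = np.sort(np.concatenate(test_idx))
    train_idx = np.setdiff1d(np.arange(n), test_idx)
    return train_idx, test_idx


# ---------------------------------------------------------------------------
# ROC machinery

def roc_curve_points(scores: np.ndarray, labels: np.ndarray):
    """Empirical ROC curve from positive-class scores.

    Returns (fpr, tpr) arrays, anchored at (0,0) and (1,1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    distinct = np.r_[np.diff(s) != 0, True]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(~y)[distinct]
    tpr = np.r_[0.0, tps / max(y.sum(), 1)]
    fpr = np.r_[0.0, fps / max((~y).sum(), 1)]
    return fpr, tpr


def auc_trapezoid(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


def f1_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximising F1 for the positive class.

    Scans midpoints between consecutive distinct scores (plus sentinels
    below the minimum and above the maximum); ties resolve to the lowest
    threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if not labels.any():
        raise StatsPreconditionError("no positive labels; F1 undefined")
    uniq = np.unique(scores)
    cand = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    best_f1, best_thr = -1.0, cand[0]
    for thr in cand:
        pred = scores > thr
        tp = np.sum(pred & labels)
        fp = np.sum(pred & ~labels)
        fn = np.sum(~pred & labels)
        f1 = 2 * tp / max(2 * tp + fp + fn, 1)
        if f1 > best_f1 + 1e-12:
            best_f1, best_thr = f1, thr
    return float(best_thr)


def confusion_report(scores, labels, threshold: float) -> dict:
    """Confusion matrix and derived rates at a decision threshold.

    Balanced accuracy is exactly (sensitivity + specificity) / 2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pred = scores > threshold
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    tn = int(np.sum(~pred & ~labels))
    fn = int(np.sum(~pred & labels))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return {
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "sensitivity": sens,
        "specificity": spec,
        "balanced_accuracy": (sens + spec) / 2.0,
    }


# ---------------------------------------------------------------------------
# hyperparameter search

def _sample_param(rng, kind_spec):
    kind = kind_spec[0]
    if kind == "int":
        return int(rng.integers(kind_spec[1], kind_spec[2] + 1))
    if kind == "float":
        return float(rng.uniform(kind_spec[1], kind_spec[2]))
    if kind == "cat":
        return kind_spec[1][int(rng.integers(0, len(kind_spec[1])))]
    raise ConfigError(f"unknown parameter kind {kind!r}")


def _tpe_suggest(rng, spec, history, gamma=0.25, n_candidates=24, n_startup=10):
    """One TPE-style suggestion: model good vs. rest densities per parameter."""
    if len(history) < n_startup:
        return {k: _sample_param(rng, v) for k, v in spec.items()}
    hist = sorted(history, key=lambda h: -h[1])
    n_good = max(1, int(np.ceil(gamma * len(hist))))
    good = [h[0] for h in hist[:n_good]]
    rest = [h[0] for h in hist[n_good:]] or good
    out = {}
    for name, kind_spec in spec.items():
        kind = kind_spec[0]
        if kind == "cat":
            choices = list(kind_spec[1])
            gcount = np.array([sum(1 for g in good if g[name] == c) for c in choices]) + 1.0
            rcount = np.array([sum(1 for r in rest if r[name] == c) for c in choices]) + 1.0
            w = (gcount / gcount.sum()) / (rcount / rcount.sum())
            w /= w.sum()
            out[name] = choices[int(rng.choice(len(choices), p=w))]
            continue
        lo, hi = kind_spec[1], kind_spec[2]
        gv = np.array([float(g[name]) for g in good])
        rv = np.array([float(r[name]) for r in rest])
        cands = np.array(
            [_sample_param(rng, kind_spec) for _ in range(n_candidates)], dtype=float
        )
        def _density(vals, at):
            if len(np.unique(vals)) < 2:
                width = max(hi - lo, 1e-9)
                return np.exp(-(((at - vals.mean()) / (0.2 * width)) ** 2))
            return gaussian_kde(vals)(at)
        score = _density(gv, cands) / np.maximum(_density(rv, cands), 1e-12)
        best = cands[int(np.argmax(score))]
        out[name] = int(round(best)) if kind == "int" else float(best)
    return out


def _make_rf(params: dict, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        class_weight="balanced", random_state=seed, n_jobs=1, **params
    )


def _cv_auc(X, y, params, folds, seed) -> list[float]:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for k, (tr, va) in enumerate(skf.split(X, y)):
        model = _make_rf(params, seed + k)
        model.fit(X[tr], y[tr])
        s = model.predict_proba(X[va])[:, 1]
        aucs.append(auc_trapezoid(*roc_curve_points(s, y[va])))
    return aucs


def tune(
    X: np.ndarray, y: np.ndarray, spec: ClassifierSpec
) -> tuple[dict, list[float]]:
    """Maximise mean stratified-CV AUC over the search budget.

    Every fit balances classes automatically; the sampler is TPE-style
    (adaptive) by default with ``sampler="random"`` as fallback. Fully
    seeded; returns (best parameters, per-trial mean CV AUCs).
    """
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise StatsPreconditionError("training data contains a single class")
    if np.min(np.bincount(y)) < spec.cv_folds:
        raise StatsPreconditionError("a class has fewer members than CV folds")
    rng = np.random.default_rng(spec.seed)
    history: list[tuple[dict, float]] = []
    trial_aucs = []
    seen = set()
    for t in range(spec.n_trials):
        if spec.sampler == "tpe":
            params = _tpe_suggest(rng, spec.space, history)
        else:
            params = {k: _sample_param(rng, v) for k, v in spec.space.items()}
        key = tuple(sorted((k, str(v)) for k, v in params.items()))
        if key in seen:
            if len(seen) >= _space_size(spec.space):
                break  # finite space exhausted
            continue
        seen.add(key)
        mean_auc = float(np.mean(_cv_auc(X, y, params, spec.cv_folds, spec.seed)))
        history.append((params, mean_auc))
        trial_aucs.append(mean_auc)
    best_params, _ = max(history, key=lambda h: h[1])
    return best_params, trial_aucs


def _space_size(space: dict) -> float:
    size = 1.0
    for kind_spec in space.values():
        if kind_spec[0] == "int":
            size *= kind_spec[2] - kind_spec[1] + 1
        elif kind_spec[0] == "cat":
            size *= len(kind_spec[1])
        else:
            return float("inf")
    return size


# ---------------------------------------------------------------------------
# final fit, bootstrap, importances

def fit_and_test(
    X_train, y_train, X_test, y_test, params: dict, seed: int = 0
) -> tuple[RandomForestClassifier, dict]:
    """Fit on the full training set only; evaluate ROC/AUC on the test set."""
    model = _make_rf(params, seed)
    model.fit(X_train, np.asarray(y_train).astype(int))
    out: dict = {}
    y_test = np.asarray(y_test).astype(int)
    if len(np.unique(y_test)) < 2:
        out["test_auc"] = None
        out["note"] = "test set single-class; AUC undefined"
        out["scores"] = model.predict_proba(X_test)[:, 1]
        return model, out
    scores = model.predict_proba(X_test)[:, 1]
    fpr, tpr = roc_curve_points(scores, y_test)
    out.update(
        scores=scores,
        roc_fpr=fpr,
        roc_tpr=tpr,
        test_auc=auc_trapezoid(fpr, tpr),
    )
    return model, out


def bootstrap_stability(
    X_train, y_train, X_test, y_test, params: dict, n_boot: int = 200, seed: int = 0
) -> dict:
    """Refit on training resamples (with replacement), evaluate on the
    fixed test set; percentile 95% CI over the resample AUCs."""
    rng = np.random.default_rng(seed)
    y_train = np.asarray(y_train).astype(int)
    y_test = np.asarray(y_test).astype(int)
    n = len(y_train)
    aucs = []
    redraws = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y_train[idx])) > 1:
                break
            redraws += 1
        model = _make_rf(params, seed + b + 1)
        model.fit(X_train[idx], y_train[idx])
        s = model.predict_proba(X_test)[:, 1]
        aucs.append(auc_trapezoid(*roc_curve_points(s, y_test)))
    aucs = np.array(aucs)
    return {
        "mean": float(aucs.mean()),
        "ci_low": float(np.percentile(aucs, 2.5)),
        "ci_high": float(np.percentile(aucs, 97.5)),
        "min": float(aucs.min()),
        "max": float(aucs.max()),
        "aucs": aucs.tolist(),
        "n_redrawn": redraws,
    }


def importance_ranking(
    model: RandomForestClassifier, feature_names: list[str]
) -> list[tuple[str, float]]:
    """Impurity importances normalised to sum 1, descending."""
    imp = np.asarray(model.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    order = np.argsort(-imp)
    return [(feature_names[i], float(imp[i])) for i in order]


# ---------------------------------------------------------------------------
# end-to-end

def run_classifier(
    features: pd.DataFrame, cohort: pd.DataFrame, spec: ClassifierSpec
) -> ClassifierReport:
    """The full evaluation protocol on a feature table + cohort.

    Split (stratified hold-out) -> tune (CV on train only) -> final fit ->
    test ROC/AUC -> F1 threshold on test scores -> confusion metrics ->
    bootstrap stability -> importances. Rows whose group is not the
    positive class are the negative class.
    """
    merged = features.join(cohort.set_index("subject_id"), how="inner")
    cols = list(spec.feature_columns)
    X = np.column_stack(
        [
            (merged["sex"] == "M").to_numpy(float)
            if c == "sex"
            else merged[c].to_numpy(float)
            for c in cols
        ]
    )
    y = merged["_positive"].to_numpy(int) if "_positive" in merged else (
        merged["group"].isin(
            spec.positive_class.split("+")
        ).to_numpy(int)
    )
    train, test = stratified_split(y, spec.test_fraction, seed=spec.seed)
    best_params, trial_aucs = tune(X[train], y[train], spec)
    cv_aucs = _cv_auc(X[train], y[train], best_params, spec.cv_folds, spec.seed)
    model, fit_out = fit_and_test(
        X[train], y[train], X[test], y[test], best_params, seed=spec.seed
    )
    scores = fit_out["scores"]
    thr = f1_threshold(scores, y[test]) if y[test].any() else 0.5
    conf = confusion_report(scores, y[test], thr)
    boot = bootstrap_stability(
        X[train], y[train], X[test], y[test], best_params,
        n_boot=spec.n_boot, seed=spec.seed + 1,
    ) if spec.n_boot > 0 else None
    return ClassifierReport(
        cv_aucs=[float(a) for a in cv_aucs],
        cv_auc_mean=float(np.mean(cv_aucs)),
        best_params=best_params,
        trial_aucs=trial_aucs,
        test_auc=fit_out.get("test_auc"),
        roc_fpr=list(map(float, fit_out.get("roc_fpr", []))),
        roc_tpr=list(map(float, fit_out.get("roc_tpr", []))),
        threshold_default=0.5,
        threshold_f1=float(thr),
        confusion=conf,
        sensitivity=conf["sensitivity"],
        specificity=conf["specificity"],
        balanced_accuracy=conf["balanced_accuracy"],
        bootstrap=boot,
        importances=importance_ranking(model, cols),
        notes=[fit_out["note"]] if "note" in fit_out else [],
    )
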