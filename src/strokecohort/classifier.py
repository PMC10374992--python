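"""Multiclass L1-penalized logistic reclassification of undetermined cases.

The model is trained on cases with evident or probable etiology (the truth
set), tuned by stratified five-fold cross-validation maximizing macro
one-vs-rest AUC, evaluated on a held-out 15% split, and then applied to
incompletely investigated cases of undetermined etiology.

Objective: minimize  -log L(W, b) + alpha * ||W||_1  (intercepts unpenalized),
fitted with the saga solver; ``alpha`` is the regularization strength (the
reciprocal of sklearn's ``C``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import softmax
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold

CLASS_ORDER = ("CE", "LAA", "SAO")

CONTINUOUS_FEATURES = ("age", "sbp", "dbp", "bmi")
CATEGORICAL_FEATURES = (
    "region_id", "sex", "urban", "diabetes", "chd", "hypertension", "bp_meds",
    "smoker", "drinker", "family_history_stroke", "health_insurance",
    "any_cardioaortic_source",
)
DEFAULT_ALPHA_GRID = tuple(np.logspace(-3.0, 3.0, 20))


def build_feature_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Predictor columns for the classifier.

    Baseline risk factors plus the cardioaortic-source screening indicator
    (any source: yes / no / unknown — "unknown" is an explicit level, not
    imputed), since source screening is available from record review even for
    incompletely investigated cases.
    """
    X = cohort.loc[:, list(CONTINUOUS_FEATURES)].copy()
    for col in CATEGORICAL_FEATURES:
        if col == "any_cardioaortic_source":
            src = cohort["cardioaortic_source"]
            X[col] = np.where(src == "unknown", "unknown",
                              np.where(src == "none", "no", "yes"))
        else:
            X[col] = cohort[col].astype(str)
    return X


class FeatureEncoder:
    """Standardize continuous columns, one-hot encode categoricals.

    Fitted on the training split only; the identical encoding is applied to
    test and undetermined cases (levels unseen in training map to all-zero
    indicators).  Fully described by plain data so the model artifact can
    round-trip through JSON.
    """

    def fit(self, X: pd.DataFrame) -> "FeatureEncoder":
        self.continuous_ = [c for c in CONTINUOUS_FEATURES if c in X.columns]
        self.categorical_ = [c for c in CATEGORICAL_FEATURES if c in X.columns]
        self.means_ = {c: float(X[c].mean()) for c in self.continuous_}
        sds = {c: float(X[c].std(ddof=0)) for c in self.continuous_}
        self.scales_ = {c: (s if s > 0 else 1.0) for c, s in sds.items()}
        self.categories_ = {c: sorted(X[c].astype(str).unique()) for c in self.categorical_}
        self.feature_names_ = list(self.continuous_) + [
            f"{c}={lvl}" for c in self.categorical_ for lvl in self.categories_[c]
        ]
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        cols = [
            (X[c].to_numpy(float) - self.means_[c]) / self.scales_[c] for c in self.continuous_
        ]
        for c in self.categorical_:
            vals = X[c].astype(str).to_numpy()
            for lvl in self.categories_[c]:
                cols.append((vals == lvl).astype(float))
        return np.column_stack(cols)

    def to_dict(self) -> dict:
        return {
            "continuous": self.continuous_, "categorical": self.categorical_,
            "means": self.means_, "scales": self.scales_, "categories": self.categories_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureEncoder":
        enc = cls()
        enc.continuous_ = list(d["continuous"])
        enc.categorical_ = list(d["categorical"])
        enc.means_ = {k: float(v) for k, v in d["means"].items()}
        enc.scales_ = {k: float(v) for k, v in d["scales"].items()}
        enc.categories_ = {k: list(v) for k, v in d["categories"].items()}
        enc.feature_names_ = list(enc.continuous_) + [
            f"{c}={lvl}" for c in enc.categorical_ for lvl in enc.categories_[c]
        ]
        return enc


class SubtypeClassifier:
    """sklearn-style multinomial logistic classifier with an L1 penalty.

    Parameters
    ----------
    alpha : float
        L1 regularization strength (sklearn ``C = 1/alpha``).  Ignored when
        ``alpha_grid`` is given.
    alpha_grid : sequence of float, optional
        When set, ``fit`` tunes alpha by stratified ``cv``-fold cross-validation
        maximizing macro one-vs-rest AUC, then refits on all training data.
    """

    def __init__(self, alpha: float = 1.0, alpha_grid=None, cv: int = 5,
                 max_iter: int = 20000, tol: float = 1e-5, random_state: int | None = None):
        self.alpha = alpha
        self.alpha_grid = alpha_grid
        self.cv = cv
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {"alpha": self.alpha, "alpha_grid": self.alpha_grid, "cv": self.cv,
                "max_iter": self.max_iter, "tol": self.tol, "random_state": self.random_state}

    def set_params(self, **params) -> "SubtypeClassifier":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- fitting ---------------------------------------------------------

    def _fit_encoded(self, Z: np.ndarray, y: np.ndarray, alpha: float,
                     max_iter: int | None = None, strict: bool = True) -> LogisticRegression:
        max_iter = self.max_iter if max_iter is None else max_iter
        lr = LogisticRegression(
            l1_ratio=1.0, C=1.0 / alpha, solver="saga", max_iter=max_iter,
            tol=self.tol, random_state=self.random_state,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # saga ConvergenceWarning handled below
            lr.fit(Z, y)
        if lr.n_iter_.max() >= max_iter:
            msg = (f"L1 logistic fit did not converge in {max_iter} iterations "
                   f"(alpha={alpha:g}); final n_iter={lr.n_iter_.tolist()}")
            if strict:
                raise RuntimeError(msg)
            warnings.warn(msg)
        return lr

    def fit(self, X: pd.DataFrame, y) -> "SubtypeClassifier":
        y = np.asarray(y, dtype=object)
        classes = [c for c in CLASS_ORDER if c in set(y)] or sorted(set(y))
        if len(classes) < 2:
            raise ValueError("need at least 2 classes to fit")
        self.encoder_ = FeatureEncoder().fit(X)
        Z = self.encoder_.transform(X)
        if self.alpha_grid is not None:
            # fold fits are iteration-capped (ranking is robust); only the
            # final refit below must converge to tolerance
            self.alpha_, self.cv_trace_ = tune_l1_strength(
                X, y, self.alpha_grid, k=self.cv, seed=self.random_state,
                max_iter=min(self.max_iter, 2000), tol=self.tol,
            )
        else:
            self.alpha_ = float(self.alpha)
            self.cv_trace_ = None
        if np.isinf(self.alpha_):
            # fully penalized limit: all coefficients zero, predictions are the
            # training class frequencies
            self.classes_ = np.array(classes, dtype=object)
            self.coef_ = np.zeros((len(classes), Z.shape[1]))
            freqs = np.array([(y == c).mean() for c in classes])
            self.intercept_ = np.log(freqs)
            self.feature_names_ = list(self.encoder_.feature_names_)
            self.n_features_in_ = Z.shape[1]
            return self
        lr = self._fit_encoded(Z, y, self.alpha_, strict=not getattr(self, "_cv_cap", False))
        order = [list(lr.classes_).index(c) for c in classes]
        self.classes_ = np.array(classes, dtype=object)
        if len(classes) == 2:
            # sklearn stores a single row for binary problems
            coef = np.vstack([-lr.coef_[0] / 2, lr.coef_[0] / 2])
            intercept = np.array([-lr.intercept_[0] / 2, lr.intercept_[0] / 2])
            self.coef_ = coef[order]
            self.intercept_ = intercept[order]
        else:
            self.coef_ = lr.coef_[order]
            self.intercept_ = lr.intercept_[order]
        self.feature_names_ = list(self.encoder_.feature_names_)
        self.n_features_in_ = Z.shape[1]
        return self

    # -- prediction ------------------------------------------------------

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        Z = self.encoder_.transform(X)
        return Z @ self.coef_.T + self.intercept_

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return softmax(self.decision_function(X), axis=1)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        # argmax with ties resolved by fixed class order (CE, LAA, SAO)
        p = self.predict_proba(X)
        return self.classes_[np.argmax(p, axis=1)]

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "classes": self.classes_.tolist(),
            "feature_names": self.feature_names_,
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_.tolist(),
            "alpha": self.alpha_,
            "cv_trace": (self.cv_trace_.to_dict(orient="list") if self.cv_trace_ is not None else None),
            "random_state": self.random_state,
            "encoder": self.encoder_.to_dict(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SubtypeClassifier":
        model = cls(alpha=d["alpha"], random_state=d.get("random_state"))
        model.classes_ = np.array(d["classes"], dtype=object)
        model.coef_ = np.array(d["coef"], dtype=float)
        model.intercept_ = np.array(d["intercept"], dtype=float)
        model.alpha_ = float(d["alpha"])
        model.feature_names_ = list(d["feature_names"])
        model.encoder_ = FeatureEncoder.from_dict(d["encoder"])
        model.cv_trace_ = pd.DataFrame(d["cv_trace"]) if d.get("cv_trace") else None
        model.n_features_in_ = model.coef_.shape[1]
        return model

    @classmethod
    def from_json(cls, path) -> "SubtypeClassifier":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---- module-level operations (thin wrappers) ---------------------------

def split_cohort(cases: pd.DataFrame, y, fraction: float = 0.85, seed: int | None = None):
    """Disjoint, exhaustive train/test partition stratified by class label.

    The training size is ``round(fraction * n)`` (up to +-1 after per-class
    rounding).  A class absent from either side raises a warning, not an error.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    if len(cases) < 20:
        raise ValueError("need at least 20 cases to split")
    y = np.asarray(y, dtype=object)
    rng = np.random.default_rng(seed)
    n_train_target = int(round(fraction * len(cases)))
    train_mask = np.zeros(len(cases), dtype=bool)
    # largest-remainder allocation of the train budget across classes
    classes, counts = np.unique(y, return_counts=True)
    exact = counts * fraction
    base = np.floor(exact).astype(int)
    short = n_train_target - base.sum()
    order = np.argsort(-(exact - base))
    for i in order[:max(short, 0)]:
        base[i] += 1
    for cls, k in zip(classes, base):
        idx = np.flatnonzero(y == cls)
        take = rng.permutation(idx)[:k]
        train_mask[take] = True
    for cls in classes:
        for side, mask in (("train", train_mask), ("test", ~train_mask)):
            if not np.any((y == cls) & mask):
                warnings.warn(f"class {cls!r} absent from {side} split")
    return cases.iloc[train_mask], cases.iloc[~train_mask], y[train_mask], y[~train_mask]


def _macro_ovr_auc(y_true, proba, classes) -> float:
    aucs = []
    for k, cls in enumerate(classes):
        pos = (np.asarray(y_true, dtype=object) == cls).astype(int)
        if 0 < pos.sum() < len(pos):
            aucs.append(roc_auc_score(pos, proba[:, k]))
    return float(np.mean(aucs))


def tune_l1_strength(X: pd.DataFrame, y, strength_grid, k: int = 5, seed: int | None = None,
                     max_iter: int = 2000, tol: float = 1e-5):
    """Grid value maximizing mean k-fold macro one-vs-rest AUC.

    Folds are stratified by class; ties break toward the weakest penalty.  If a
    shuffled fold still lacks a class in its training part, the folds are
    redrawn once before giving up.
    """
    grid = sorted(float(a) for a in strength_grid)
    if not grid or grid[0] <= 0:
        raise ValueError("strength_grid must be non-empty with all strengths > 0")
    y = np.asarray(y, dtype=object)
    classes = np.unique(y)

    def make_folds(rs):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
        folds = list(skf.split(np.zeros(len(y)), y))
        ok = all(len(np.unique(y[tr])) == len(classes) for tr, _ in folds)
        return folds, ok

    base_seed = 0 if seed is None else int(seed)
    folds, ok = make_folds(base_seed)
    if not ok:
        folds, ok = make_folds(base_seed + 1)
        if not ok:
            raise RuntimeError("degenerate cross-validation fold: a training fold lacks a class")

    mean_auc = []
    for alpha in grid:
        scores = []
        for tr, va in folds:
            model = SubtypeClassifier(alpha=alpha, max_iter=max_iter, tol=tol,
                                      random_state=base_seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model._cv_cap = True
                model.fit(X.iloc[tr], y[tr])
            proba = model.predict_proba(X.iloc[va])
            scores.append(_macro_ovr_auc(y[va], proba, model.classes_))
        mean_auc.append(float(np.mean(scores)))
    trace = pd.DataFrame({"alpha": grid, "mean_cv_auc": mean_auc})
    best = int(np.argmax(mean_auc))  # first max => smallest alpha on ties
    return grid[best], trace


def fit_multiclass_l1(X: pd.DataFrame, y, alpha: float, seed: int | None = None,
                      **kwargs) -> SubtypeClassifier:
    return SubtypeClassifier(alpha=alpha, random_state=seed, **kwargs).fit(X, y)


# ---- evaluation --------------------------------------------------------

@dataclass
class ClassMetrics:
    auc: float
    auc_ci: tuple[float, float]
    ppv: float
    sensitivity: float
    f1: float
    defined: bool = True


@dataclass
class EvaluationReport:
    classes: list[str]
    per_class: dict[str, ClassMetrics]
    accuracy: float
    accuracy_ci: tuple[float, float]
    macro_auc: float
    n_test: int
    confusion: list[list[int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "per_class": {
                c: {"auc": m.auc, "auc_ci": list(m.auc_ci), "ppv": m.ppv,
                    "sensitivity": m.sensitivity, "f1": m.f1, "defined": m.defined}
                for c, m in self.per_class.items()
            },
            "accuracy": self.accuracy, "accuracy_ci": list(self.accuracy_ci),
            "macro_auc": self.macro_auc, "n_test": self.n_test, "confusion": self.confusion,
        }


def _point_metrics(y_true, proba, pred, classes):
    cm = confusion_matrix(y_true, pred, labels=list(classes))
    out = {}
    for k, cls in enumerate(classes):
        pos = (np.asarray(y_true, dtype=object) == cls).astype(int)
        if pos.sum() == 0 or pos.sum() == len(pos):
            out[cls] = (np.nan, np.nan, np.nan, np.nan, False)
            continue
        auc = roc_auc_score(pos, proba[:, k])
        tp = cm[k, k]
        ppv = tp / cm[:, k].sum() if cm[:, k].sum() > 0 else np.nan
        sens = tp / cm[k, :].sum()
        f1 = (2 * ppv * sens / (ppv + sens)) if (ppv + sens) > 0 and not np.isnan(ppv) else np.nan
        out[cls] = (auc, ppv, sens, f1, True)
    acc = np.trace(cm) / cm.sum()
    return out, acc, cm


def evaluate(model: SubtypeClassifier, X_test: pd.DataFrame, y_test,
             n_bootstrap: int = 2000, seed: int | None = None) -> EvaluationReport:
    """Held-out performance: one-vs-rest AUC, PPV, sensitivity, F1, accuracy.

    AUC is the rank statistic with ties counted one-half; PPV/sensitivity/F1
    come from the arg-max confusion matrix; 95% CIs are percentile intervals
    from a class-stratified bootstrap.  A class absent from the test set has
    its metrics flagged undefined (NaN), not zero.
    """
    if len(X_test) == 0:
        raise ValueError("test set is empty")
    y_test = np.asarray(y_test, dtype=object)
    proba = model.predict_proba(X_test)
    pred = model.classes_[np.argmax(proba, axis=1)]
    classes = list(model.classes_)
    point, acc, cm = _point_metrics(y_test, proba, pred, classes)

    rng = np.random.default_rng(seed)
    strata = [np.flatnonzero(y_test == c) for c in np.unique(y_test)]
    boot_auc = {c: [] for c in classes}
    boot_acc = []
    for _ in range(n_bootstrap):
        idx = np.concatenate([rng.choice(s, size=len(s), replace=True) for s in strata])
        bp, bacc, _ = _point_metrics(y_test[idx], proba[idx], pred[idx], classes)
        boot_acc.append(bacc)
        for c in classes:
            boot_auc[c].append(bp[c][0])
    per_class = {}
    for c in classes:
        auc, ppv, sens, f1, defined = point[c]
        vals = np.array(boot_auc[c], dtype=float)
        vals = vals[~np.isnan(vals)]
        ci = (float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5))) \
            if defined and len(vals) else (np.nan, np.nan)
        per_class[c] = ClassMetrics(auc, ci, ppv, sens, f1, defined)
    defined_aucs = [m.auc for m in per_class.values() if m.defined]
    acc_ci = (float(np.percentile(boot_acc, 2.5)), float(np.percentile(boot_acc, 97.5))) \
        if n_bootstrap else (np.nan, np.nan)
    return EvaluationReport(
        classes=classes, per_class=per_class, accuracy=float(acc), accuracy_ci=acc_ci,
        macro_auc=float(np.mean(defined_aucs)), n_test=len(y_test),
        confusion=cm.astype(int).tolist(),
    )


def apply_to_undetermined(model: SubtypeClassifier, cohort: pd.DataFrame,
                          assignments: pd.DataFrame) -> pd.DataFrame:
    """Predict subtypes for incompletely investigated undetermined cases.

    Selection: assigned UNDETERMINED with undetermined_kind
    ``incomplete_investigation``.  Returns case_id, per-class probabilities
    (p_CE, p_LAA, p_SAO) and the arg-max label; empty with a warning when no
    case qualifies.
    """
    merged = cohort.merge(assignments[["case_id", "subtype", "undetermined_kind"]],
                          on="case_id", how="left", suffixes=("", "_ccs"))
    key = "subtype_ccs" if "subtype_ccs" in merged.columns else "subtype"
    sel = merged[(merged[key] == "UNDETERMINED")
                 & (merged["undetermined_kind"] == "incomplete_investigation")]
    cols = ["case_id"] + [f"p_{c}" for c in model.classes_] + ["predicted"]
    if len(sel) == 0:
        warnings.warn("no incompletely investigated undetermined cases to reclassify")
        return pd.DataFrame(columns=cols)
    proba = model.predict_proba(build_feature_frame(sel))
    out = pd.DataFrame({"case_id": sel["case_id"].to_numpy()})
    for k, c in enumerate(model.classes_):
        out[f"p_{c}"] = proba[:, k]
    out["predicted"] = model.classes_[np.argmax(proba, axis=1)]
    return out
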