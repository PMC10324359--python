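"""Motor-status decoding: 32-feature table and nested cross-validation.

Features are the periodic (peak) band powers of the eight canonical bands in
four regions (PMC, M1, SPL, STN) per 2 s epoch.  A gradient-boosted
decision-tree ensemble (XGBoost) classifies the five motor statuses with a
nested stratified 5-fold cross-validation: the outer loop estimates
generalization, the inner loop tunes hyperparameters by random search on the
training folds only.  Class imbalance is handled by random undersampling to
the minority class and missing regions by train-fold mean imputation, both
recomputed inside every outer training fold so no test information leaks
into training.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .errors import InsufficientDataError, InvalidArgumentError
from .preprocess import FEATURE_REGIONS, Epoch
from .spectral import BANDS, band_power_table, fit_spectral_model, welch_psd

__all__ = [
    "FEATURE_COLUMNS",
    "DEFAULT_SEARCH_SPACE",
    "ClassificationResult",
    "build_feature_table",
    "impute_missing",
    "undersample",
    "nested_cv_classify",
    "feature_importance",
]

#: the 32 feature columns: 4 regions x 8 bands
FEATURE_COLUMNS = [f"{region}_{band}" for region in FEATURE_REGIONS
                   for band in BANDS]

META_COLUMNS = ["label", "subject", "med_state", "trial_id"]

#: random-search ranges for the gradient-boosted trees
DEFAULT_SEARCH_SPACE = {
    "n_estimators": (50, 500),          # uniform integer
    "max_depth": (2, 10),               # uniform integer
    "learning_rate": (0.01, 0.3),       # log-uniform
    "subsample": (0.5, 1.0),            # uniform
    "colsample_bytree": (0.5, 1.0),     # uniform
    "min_child_weight": (1, 10),        # uniform integer
}


def _pool_region(region: str) -> str:
    """Bipolar STN channels of both sides pool into one STN feature region."""
    return "STN" if region.startswith("STN") else region


def build_feature_table(epochs: list[Epoch],
                        fit_range: tuple[float, float] = (2.0, 200.0),
                        n_fft: int = 2000, n_overlap: int = 1000,
                        compensate_band: tuple[float, float] | None = None,
                        ) -> pd.DataFrame:
    """One row per epoch: mean periodic band power per feature region.

    Each channel of an epoch is Welch-transformed and parameterized into
    periodic and aperiodic components; a region's feature is the mean
    periodic band power across that region's channels.  Regions with no
    usable channel yield missing values; epochs with no usable channel in
    any feature region are dropped with a warning.

    ``compensate_band``: when the epochs were band-pass filtered, pass the
    filter edges so the PSD is divided by the known filter power response
    before fitting (prevents the roll-off skirts from masquerading as
    spectral peaks).
    """
    from .preprocess import filter_power_response

    correction: np.ndarray | None = None
    rows = []
    for ep in epochs:
        region_powers: dict[str, list[dict[str, float]]] = {}
        for ch, region in enumerate(ep.regions):
            pooled = _pool_region(region)
            if pooled not in FEATURE_REGIONS:
                continue
            spec = welch_psd(ep.data[ch], ep.fs, n_fft=n_fft, n_overlap=n_overlap)
            if compensate_band is not None:
                if correction is None:
                    correction = np.maximum(filter_power_response(
                        spec.freqs, ep.fs, band=compensate_band), 1e-8)
                spec.psd = spec.psd / correction
            model = fit_spectral_model(spec, fit_range=fit_range)
            region_powers.setdefault(pooled, []).append(band_power_table(model))
        if not region_powers:
            warnings.warn(
                f"epoch {ep.trial_id}:{ep.window_index} has no usable channel "
                "in any feature region; dropped", stacklevel=2)
            continue
        row: dict = {"label": ep.label, "subject": ep.subject,
                     "med_state": ep.med_state, "trial_id": ep.trial_id}
        for region in FEATURE_REGIONS:
            tables = region_powers.get(region)
            for band in BANDS:
                col = f"{region}_{band}"
                row[col] = (float(np.mean([t[band] for t in tables]))
                            if tables else np.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=META_COLUMNS + FEATURE_COLUMNS)


def impute_missing(train: pd.DataFrame, test: pd.DataFrame | None = None,
                   ) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Mean imputation with means computed on the training table only."""
    cols = [c for c in FEATURE_COLUMNS if c in train.columns]
    means = train[cols].mean()
    dead = means[means.isna()].index.tolist()
    if dead:
        raise InvalidArgumentError(
            f"all-missing feature column(s) in train: {', '.join(dead)}")
    train = train.copy()
    train[cols] = train[cols].fillna(means)
    if test is not None:
        test = test.copy()
        test[cols] = test[cols].fillna(means)
    return train, test


def undersample(table: pd.DataFrame, seed: int | np.random.Generator = 0,
                ) -> pd.DataFrame:
    """Randomly downsample every class to the minority-class count."""
    counts = table["label"].value_counts()
    if (counts == 0).any() or len(counts) < 2:
        raise InvalidArgumentError("undersample needs >= 2 non-empty classes")
    n_min = int(counts.min())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keep_idx = []
    for label in sorted(counts.index):
        idx = table.index[table["label"] == label].to_numpy()
        if idx.size > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep_idx.append(np.sort(idx))
    return table.loc[np.concatenate(keep_idx)]


# --------------------------------------------------------------------------
# Nested cross-validation
# --------------------------------------------------------------------------

@dataclass
class ClassificationResult:
    """Outputs of the nested cross-validated classifier."""

    classes: list[str]
    fold_accuracies: list[float]            # percent, one per outer fold
    mean_accuracy: float                    # percent
    sd_accuracy: float                      # percent
    auc_macro: float                        # macro one-vs-rest
    roc_curves: dict[str, tuple[list, list]]  # per class: (fpr, tpr)
    confusion: np.ndarray                   # pooled counts, rows = true class
    importances: pd.Series                  # normalized gain, sums to 1
    fold_params: list[dict] = field(default_factory=list)
    fold_sizes: list[int] = field(default_factory=list)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "fold_accuracies": self.fold_accuracies,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "auc_macro": self.auc_macro,
            "confusion": self.confusion.tolist(),
            "importances": {k: float(v) for k, v in self.importances.items()},
            "fold_params": self.fold_params,
            "fold_sizes": self.fold_sizes,
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def _sample_params(rng: np.random.Generator) -> dict:
    lo, hi = DEFAULT_SEARCH_SPACE["learning_rate"]
    return {
        "n_estimators": int(rng.integers(*DEFAULT_SEARCH_SPACE["n_estimators"],
                                         endpoint=True)),
        "max_depth": int(rng.integers(*DEFAULT_SEARCH_SPACE["max_depth"],
                                      endpoint=True)),
        "learning_rate": float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
        "subsample": float(rng.uniform(*DEFAULT_SEARCH_SPACE["subsample"])),
        "colsample_bytree": float(
            rng.uniform(*DEFAULT_SEARCH_SPACE["colsample_bytree"])),
        "min_child_weight": int(
            rng.integers(*DEFAULT_SEARCH_SPACE["min_child_weight"],
                         endpoint=True)),
    }


def _make_model(params: dict, seed: int, n_classes: int) -> XGBClassifier:
    objective = "multi:softprob" if n_classes > 2 else "binary:logistic"
    return XGBClassifier(
        objective=objective, tree_method="hist",
        n_jobs=1, random_state=seed, verbosity=0, **params)


def _gain_importance(model: XGBClassifier, feature_names: list[str]) -> pd.Series:
    booster = model.get_booster()
    booster.feature_names = list(feature_names)
    gains = booster.get_score(importance_type="gain")
    out = pd.Series(0.0, index=feature_names)
    for name, g in gains.items():
        out[name] = g
    total = out.sum()
    return out / total if total > 0 else out


def nested_cv_classify(table: pd.DataFrame, n_search: int = 25,
                       outer_k: int = 5, inner_k: int = 5, seed: int = 0,
                       ) -> ClassificationResult:
    """Nested stratified k-fold classification of the motor statuses.

    Per outer fold: undersample the training portion to class balance, mean
    impute (train means applied to both portions), run ``n_search`` rounds of
    random hyperparameter search scored by inner stratified k-fold accuracy,
    refit the best configuration and evaluate on the untouched outer test
    fold.  Reports per-fold accuracies, macro one-vs-rest AUC on the pooled
    out-of-fold probabilities, the pooled confusion matrix and gain-based
    feature importances averaged over folds.
    """
    feats = [c for c in FEATURE_COLUMNS if c in table.columns]
    y_all = table["label"].to_numpy()
    classes = sorted(pd.unique(y_all))
    counts = pd.Series(y_all).value_counts()
    if (counts < outer_k).any():
        raise InsufficientDataError(
            f"every class needs >= {outer_k} epochs for stratification")

    rng = np.random.default_rng(seed)
    outer = StratifiedKFold(n_splits=outer_k, shuffle=True, random_state=seed)
    class_to_int = {c: i for i, c in enumerate(classes)}

    fold_acc, fold_params, fold_imps, fold_sizes = [], [], [], []
    pooled_true, pooled_pred, pooled_proba = [], [], []
    for fold, (tr_idx, te_idx) in enumerate(outer.split(table[feats], y_all)):
        train = table.iloc[tr_idx]
        test = table.iloc[te_idx]
        train = undersample(train, rng)
        train, test = impute_missing(train, test)
        x_tr = train[feats].to_numpy()
        y_tr = np.array([class_to_int[c] for c in train["label"]])
        x_te = test[feats].to_numpy()
        y_te = np.array([class_to_int[c] for c in test["label"]])

        best_score, best_params = -np.inf, None
        # the inner split cannot use more folds than the smallest class has
        # rows in the (undersampled) training portion
        inner_k_eff = min(inner_k, int(np.bincount(y_tr).min()))
        if inner_k_eff >= 2:
            inner = StratifiedKFold(n_splits=inner_k_eff, shuffle=True,
                                    random_state=seed + 1000 + fold)
            for _ in range(n_search):
                params = _sample_params(rng)
                scores = []
                for i_tr, i_va in inner.split(x_tr, y_tr):
                    m = _make_model(params, seed, len(classes))
                    m.fit(x_tr[i_tr], y_tr[i_tr])
                    scores.append(
                        float(np.mean(m.predict(x_tr[i_va]) == y_tr[i_va])))
                score = float(np.mean(scores))
                if score > best_score:
                    best_score, best_params = score, params
        else:
            warnings.warn("training fold too small for an inner search; "
                          "using default hyperparameters", stacklevel=2)
            best_params = {"n_estimators": 100, "max_depth": 4,
                           "learning_rate": 0.1, "subsample": 1.0,
                           "colsample_bytree": 1.0, "min_child_weight": 1}

        model = _make_model(best_params, seed, len(classes))
        model.fit(x_tr, y_tr)
        pred = model.predict(x_te)
        proba = model.predict_proba(x_te)
        fold_acc.append(100.0 * float(np.mean(pred == y_te)))
        fold_sizes.append(int(y_te.size))
        fold_params.append(best_params)
        fold_imps.append(_gain_importance(model, feats))
        pooled_true.append(y_te)
        pooled_pred.append(pred)
        pooled_proba.append(proba)

    y_true = np.concatenate(pooled_true)
    y_pred = np.concatenate(pooled_pred)
    proba = np.vstack(pooled_proba)

    if len(classes) > 2:
        auc = float(roc_auc_score(y_true, proba, multi_class="ovr",
                                  average="macro", labels=range(len(classes))))
    else:
        auc = float(roc_auc_score(y_true, proba[:, 1]))
    roc_curves = {}
    for ci, cname in enumerate(classes):
        fpr, tpr, _ = roc_curve((y_true == ci).astype(int), proba[:, ci])
        roc_curves[cname] = (fpr.tolist(), tpr.tolist())

    confusion = _sk_confusion(y_true, y_pred, labels=range(len(classes)))
    importances = pd.concat(fold_imps, axis=1).mean(axis=1)
    total = importances.sum()
    if total > 0:
        importances = importances / total

    return ClassificationResult(
        classes=classes, fold_accuracies=fold_acc,
        mean_accuracy=float(np.mean(fold_acc)),
        sd_accuracy=float(np.std(fold_acc)),
        auc_macro=auc, roc_curves=roc_curves, confusion=confusion,
        importances=importances, fold_params=fold_params,
        fold_sizes=fold_sizes, seed=seed)


def feature_importance(result: ClassificationResult) -> list[tuple[str, float]]:
    """Features ranked by fold-averaged normalized gain, descending."""
    ranked = result.importances.sort_values(ascending=False)
    return [(name, float(v)) for name, v in ranked.items()]
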