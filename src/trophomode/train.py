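"""Training and evaluation of the gradient-boosted trophic-mode classifier.

The classifier is a three-class XGBoost model over scaled species-level Pfam
TPM profiles. The training protocol addresses the strong class imbalance of
culture transcriptome collections (many more phototrophic than mixotrophic or
heterotrophic entries) by running feature selection on several randomly
undersampled versions of the dataset, scoring each Pfam by permutation
importance — the mean relative decrease in F1 after shuffling that Pfam's
values across the held-out samples — and retaining any Pfam whose inclusion
improves performance in at least one undersampled dataset.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    confusion_matrix,
    f1_score,
    precision_recall_fscore_support,
)
from sklearn.model_selection import (
    GridSearchCV,
    ShuffleSplit,
    StratifiedKFold,
    StratifiedShuffleSplit,
)
from xgboost import Booster, XGBClassifier

from .config import IMPORTANCE_RETAIN_SIGN, MODES, canonical_mode
from .profiles import ScalerParams, apply_scaler, fit_scaler

logger = logging.getLogger(__name__)

#: Mid-grid default hyperparameters used when grid search is skipped.
DEFAULT_HYPERPARAMS: dict = {
    "n_estimators": 100,
    "max_depth": 10,
    "learning_rate": 0.1,
    "gamma": 0.5,
    "reg_lambda": 0.5,
}

#: The hyperparameter grid evaluated by :func:`grid_search`
#: (3 * 3 * 4 * 3 * 3 = 324 combinations).
HYPERPARAM_GRID: dict[str, list] = {
    "n_estimators": [10, 100, 1000],
    "max_depth": [3, 10, 20],
    "learning_rate": [0.05, 0.1, 0.15, 0.2],
    "gamma": [0, 0.5, 1],
    "reg_lambda": [0, 0.5, 1],
}

#: Undersampled phototrophy counts used for feature selection.
UNDERSAMPLE_SIZES: tuple[int, ...] = (50, 80, 100, 120)


def _sub_seed(seed: int, stream: str) -> int:
    """Deterministic named sub-seed < 2**31 derived from a top-level seed."""
    h = hashlib.sha256(f"{seed}:{stream}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def encode_labels(labels: Sequence[str]) -> np.ndarray:
    """Map trophic-mode labels to integer codes in the canonical MODES order."""
    lut = {m: i for i, m in enumerate(MODES)}
    return np.array([lut[canonical_mode(l)] for l in labels], dtype=int)


def decode_labels(codes: Iterable[int]) -> list[str]:
    return [MODES[int(c)] for c in codes]


def make_classifier(params: Mapping | None = None, seed: int = 0) -> XGBClassifier:
    """A three-class XGBoost classifier with the package's fixed settings."""
    p = dict(DEFAULT_HYPERPARAMS)
    if params:
        p.update(params)
    return XGBClassifier(
        objective="multi:softprob",
        num_class=len(MODES),
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        **p,
    )


# ---------------------------------------------------------------------------
# Undersampling
# ---------------------------------------------------------------------------

def undersample(
    matrix: pd.DataFrame,
    labels: pd.Series,
    n_photo: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Random subset of phototrophic profiles; all mixo/heterotrophic kept.

    Sampling is without replacement and deterministic under ``seed``.
    """
    lab = labels.map(canonical_mode)
    photo_idx = lab.index[lab == "phototrophy"]
    if n_photo > len(photo_idx):
        raise ValueError(
            f"n_photo={n_photo} exceeds available phototrophic profiles ({len(photo_idx)})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(photo_idx), size=n_photo, replace=False)
    keep = photo_idx[np.sort(chosen)].tolist() + lab.index[lab != "phototrophy"].tolist()
    keep = [i for i in labels.index if i in set(keep)]  # preserve original order
    return matrix.loc[keep], lab.loc[keep]


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class F1Report:
    """Per-class precision/recall/F1, weighted F1 and the confusion matrix."""

    per_class: pd.DataFrame  # index = MODES; columns precision/recall/f1/support
    weighted_f1: float
    confusion: pd.DataFrame  # rows = true mode, cols = predicted mode


def evaluate_f1(y_true: Sequence[str], y_pred: Sequence[str]) -> F1Report:
    """Multiclass precision/recall/F1 with support-weighted mean F1."""
    if len(y_true) == 0:
        raise ValueError("empty label vectors")
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors differ in length")
    yt = [canonical_mode(l) for l in y_true]
    yp = [canonical_mode(l) for l in y_pred]
    prec, rec, f1, support = precision_recall_fscore_support(
        yt, yp, labels=list(MODES), zero_division=0
    )
    per_class = pd.DataFrame(
        {"precision": prec, "recall": rec, "f1": f1, "support": support},
        index=list(MODES),
    )
    weighted = f1_score(yt, yp, labels=list(MODES), average="weighted", zero_division=0)
    conf = pd.DataFrame(
        confusion_matrix(yt, yp, labels=list(MODES)),
        index=list(MODES),
        columns=list(MODES),
    )
    return F1Report(per_class=per_class, weighted_f1=float(weighted), confusion=conf)


def culture_accuracy(table: pd.DataFrame) -> tuple[float, float]:
    """Accuracy of predictions against expected trophic modes of cultures.

    ``table`` has one row per replicate transcriptome with columns
    ``culture_id``, ``expected_modes`` (one mode or several joined by ``|``
    when more than one mode would be biologically acceptable) and
    ``predicted_mode``. Returns ``(replicate_accuracy, culture_accuracy)``:
    the fraction of individual replicates predicted within their expected
    set, and the fraction of cultures for which *every* replicate was.
    """
    if table.empty:
        raise ValueError("empty prediction table")
    expected = table["expected_modes"].map(
        lambda s: {canonical_mode(m) for m in str(s).split("|")}
    )
    correct = [
        canonical_mode(p) in exp for p, exp in zip(table["predicted_mode"], expected)
    ]
    table = table.assign(_correct=correct)
    replicate_acc = float(np.mean(correct))
    per_culture = table.groupby("culture_id")["_correct"].all()
    return replicate_acc, float(per_culture.mean())


# ---------------------------------------------------------------------------
# Permutation importance (mean decrease in F1)
# ---------------------------------------------------------------------------

def permutation_importance(
    matrix: pd.DataFrame,
    labels: pd.Series,
    n_splits: int = 10,
    test_size: float = 0.30,
    seed: int = 0,
    params: Mapping | None = None,
    chunk_features: int = 64,
) -> pd.DataFrame:
    """Per-Pfam importance as the mean relative decrease in F1 after shuffling.

    For each of ``n_splits`` random 70/30 splits the classifier is fitted on
    the training part and scored (weighted F1) on the held-out part. Each
    feature's values are then shuffled across the held-out samples, the
    fitted model re-predicts, and the importance for that split is
    ``(F1 - F1_shuffled) / F1`` (defined as 0 when F1 is 0). Shuffling is
    applied to the held-out partition only, without refitting. A feature with
    identical values across samples is untouched by shuffling and scores
    exactly 0.

    Returns a DataFrame indexed by Pfam accession with one column per split
    (``split_0`` ...) and a ``mean_importance`` column.
    """
    y = encode_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("permutation importance requires at least 2 classes")
    X = matrix.to_numpy(dtype=float)
    features = list(matrix.columns)
    splitter = ShuffleSplit(n_splits=n_splits, test_size=test_size, random_state=_sub_seed(seed, "splits"))
    imp = np.zeros((len(features), n_splits))

    for s, (tr, te) in enumerate(splitter.split(X, y)):
        clf = make_classifier(params, seed=_sub_seed(seed, f"fit_{s}"))
        clf.fit(X[tr], y[tr])
        y_te = y[te]
        base_f1 = f1_score(y_te, clf.predict(X[te]), average="weighted", zero_division=0)
        if base_f1 == 0:
            continue  # importances stay 0 for this split
        rng = np.random.default_rng(_sub_seed(seed, f"shuffle_{s}"))
        # Features never split on by the booster cannot change any prediction
        # when shuffled, so their importance is exactly 0 for this split and
        # only the used features need re-prediction.
        used_names = clf.get_booster().get_score(importance_type="weight").keys()
        used = sorted(int(n[1:]) for n in used_names)
        X_te = X[te]
        n_te = len(te)
        for start in range(0, len(used), chunk_features):
            idxs = used[start : start + chunk_features]
            stacked = np.tile(X_te, (len(idxs), 1))
            for k, j in enumerate(idxs):
                col = stacked[k * n_te : (k + 1) * n_te, j]
                rng.shuffle(col)
            preds = clf.predict(stacked)
            for k, j in enumerate(idxs):
                f1_shuf = f1_score(
                    y_te, preds[k * n_te : (k + 1) * n_te], average="weighted", zero_division=0
                )
                imp[j, s] = (base_f1 - f1_shuf) / base_f1

    out = pd.DataFrame(
        imp, index=pd.Index(features, name="pfam_acc"),
        columns=[f"split_{s}" for s in range(n_splits)],
    )
    out["mean_importance"] = out.mean(axis=1)
    return out


def select_features(importances: Mapping[object, pd.Series]) -> list[str]:
    """Retain Pfams whose shuffling degraded F1 in at least one dataset.

    ``importances`` maps a dataset id (one undersampled replicate) to a
    Series of mean importance per Pfam. A Pfam is retained iff its mean
    importance is positive — shuffling reduced F1, so the feature carries
    signal — in at least one dataset. Monotone: adding a dataset never
    removes a previously retained Pfam.
    """
    retained: set[str] = set()
    for series in importances.values():
        qualifying = series[IMPORTANCE_RETAIN_SIGN * series > 0]
        retained.update(qualifying.index)
    return sorted(retained)


def feature_selection_protocol(
    matrix: pd.DataFrame,
    labels: pd.Series,
    n_photo_sizes: Sequence[int] = UNDERSAMPLE_SIZES,
    seed: int = 0,
    params: Mapping | None = None,
    n_splits: int = 10,
) -> tuple[list[str], dict[int, pd.DataFrame]]:
    """Full feature-selection run over the undersampled dataset versions.

    Scaling is refit within each undersampled dataset before importance is
    measured. Returns the selected feature list and the per-dataset
    importance tables keyed by phototroph subsample size.
    """
    tables: dict[int, pd.DataFrame] = {}
    for n_photo in n_photo_sizes:
        Xu, yu = undersample(matrix, labels, n_photo, seed=_sub_seed(seed, f"undersample_{n_photo}"))
        scaler = fit_scaler(Xu)
        Xs = apply_scaler(Xu, scaler)
        tables[n_photo] = permutation_importance(
            Xs, yu, n_splits=n_splits, seed=_sub_seed(seed, f"importance_{n_photo}"), params=params
        )
    selected = select_features({k: t["mean_importance"] for k, t in tables.items()})
    return selected, tables


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

def grid_search(
    matrix: pd.DataFrame,
    labels: pd.Series,
    grid: Mapping[str, list] | None = None,
    k: int = 5,
    seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive hyperparameter search with stratified k-fold CV.

    Every combination of the Cartesian grid is scored by mean weighted F1
    over ``k`` stratified folds; the argmax is returned, ties broken by
    first-in-grid order. Each class must have at least ``k`` members.

    Returns ``(best_params, results)`` where ``results`` has one row per
    combination with its mean score.
    """
    grid = dict(grid if grid is not None else HYPERPARAM_GRID)
    y = encode_labels(labels)
    counts = np.bincount(y, minlength=len(MODES))
    present = counts[counts > 0]
    if (present < k).any():
        raise ValueError(f"every class needs >= {k} members for {k}-fold CV; counts={counts.tolist()}")
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=_sub_seed(seed, "gridcv"))
    gs = GridSearchCV(
        make_classifier(seed=_sub_seed(seed, "gridfit")),
        param_grid=grid,
        scoring="f1_weighted",
        cv=cv,
        n_jobs=1,
    )
    gs.fit(matrix.to_numpy(dtype=float), y)
    results = pd.DataFrame(
        {"params": gs.cv_results_["params"], "mean_f1": gs.cv_results_["mean_test_score"]}
    )
    return dict(gs.best_params_), results


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Cross-validated F1 summaries: mean and standard error over splits."""

    per_class_mean: pd.Series   # index = MODES
    per_class_se: pd.Series
    weighted_mean: float
    weighted_se: float
    per_split: pd.DataFrame     # rows = splits; columns = MODES + 'weighted'


def _stratified_splits(y: np.ndarray, n_splits: int, train_size: float, seed: int):
    """Random stratified splits; a split missing a class in test is redrawn."""
    attempts = 0
    base = seed
    while True:
        sss = StratifiedShuffleSplit(
            n_splits=n_splits, train_size=train_size, random_state=base
        )
        splits = list(sss.split(np.zeros_like(y), y))
        ok = all(len(np.unique(y[te])) == len(np.unique(y)) for _, te in splits)
        if ok:
            return splits
        attempts += 1
        logger.warning("class absent from a test split; regenerating with sub-seed %d", attempts)
        base = _sub_seed(seed, f"resplit_{attempts}")
        if attempts > 20:
            raise ValueError("could not produce stratified splits covering all classes")


def cross_validate(
    matrix: pd.DataFrame,
    labels: pd.Series,
    n_splits: int = 6,
    train_size: float = 0.83,
    seed: int = 0,
    params: Mapping | None = None,
) -> CVResult:
    """Stratified shuffle-split cross-validation of the classifier.

    Trains on ``train_size`` (83% by default) of the profiles and tests on
    the remainder, preserving class proportions per split; reports per-mode
    and support-weighted F1 with standard errors over the splits.
    """
    y = encode_labels(labels)
    X = matrix.to_numpy(dtype=float)
    splits = _stratified_splits(y, n_splits, train_size, _sub_seed(seed, "cv"))
    rows = []
    for s, (tr, te) in enumerate(splits):
        clf = make_classifier(params, seed=_sub_seed(seed, f"cvfit_{s}"))
        clf.fit(X[tr], y[tr])
        rep = evaluate_f1(decode_labels(y[te]), decode_labels(clf.predict(X[te])))
        rows.append({**rep.per_class["f1"].to_dict(), "weighted": rep.weighted_f1})
    per_split = pd.DataFrame(rows)
    se = per_split.std(ddof=1) / np.sqrt(n_splits)
    return CVResult(
        per_class_mean=per_split[list(MODES)].mean(),
        per_class_se=se[list(MODES)],
        weighted_mean=float(per_split["weighted"].mean()),
        weighted_se=float(se["weighted"]),
        per_split=per_split,
    )


def learning_curve(
    matrix: pd.DataFrame,
    labels: pd.Series,
    fractions: Sequence[float] = (0.25, 0.50, 0.75, 1.0),
    n_splits: int = 6,
    test_size: float = 0.17,
    seed: int = 0,
    params: Mapping | None = None,
) -> pd.DataFrame:
    """Weighted F1 as a function of the fraction of training data used.

    A fixed stratified test partition is drawn per split; the training side
    is subsampled (stratified) to each fraction so that curves are comparable
    across fractions within a split.
    """
    y = encode_labels(labels)
    X = matrix.to_numpy(dtype=float)
    splits = _stratified_splits(y, n_splits, 1.0 - test_size, _sub_seed(seed, "lc"))
    rows = []
    for s, (tr, te) in enumerate(splits):
        rng = np.random.default_rng(_sub_seed(seed, f"lcsub_{s}"))
        for frac in fractions:
            if frac >= 1.0:
                sub = tr
            else:
                sub = []
                for cls in np.unique(y[tr]):
                    cls_idx = tr[y[tr] == cls]
                    n_keep = max(1, int(round(frac * len(cls_idx))))
                    sub.extend(rng.choice(cls_idx, size=n_keep, replace=False))
                sub = np.array(sub)
            clf = make_classifier(params, seed=_sub_seed(seed, f"lcfit_{s}_{frac}"))
            clf.fit(X[sub], y[sub])
            f1 = f1_score(y[te], clf.predict(X[te]), average="weighted", zero_division=0)
            rows.append({"split": s, "fraction": frac, "weighted_f1": float(f1)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model bundle
# ---------------------------------------------------------------------------

@dataclass
class TrophicModelBundle:
    """A trained classifier with everything needed to apply it.

    Serialized as a directory: ``features.txt`` (one Pfam per line),
    ``scaler.tsv`` (per-feature min/max), ``model.json`` (the boosted-tree
    model) and ``manifest.json`` (hyperparameters, seeds, label counts and a
    hash of the training matrix). The model is held as the underlying
    booster, which serializes to portable JSON.
    """

    features: list[str]
    scaler: ScalerParams
    booster: Booster
    hyperparams: dict
    manifest: dict = field(default_factory=dict)

    def predict_proba(self, matrix: pd.DataFrame) -> pd.DataFrame:
        """Class-probability vectors (columns in MODES order, rows as input).

        The input is zero-filled/reordered to the bundle's feature list and
        scaled with the bundle's scaler before prediction.
        """
        scaled = apply_scaler(matrix, self.scaler)
        proba = self.booster.inplace_predict(scaled.to_numpy(dtype=np.float32))
        proba = proba.astype(np.float64)
        proba /= proba.sum(axis=1, keepdims=True)  # exact simplex in float64
        return pd.DataFrame(proba, index=matrix.index, columns=list(MODES))

    def predict(self, matrix: pd.DataFrame) -> pd.Series:
        """Predicted trophic mode per profile (argmax of the probabilities)."""
        proba = self.predict_proba(matrix)
        return pd.Series(
            [MODES[i] for i in np.argmax(proba.to_numpy(), axis=1)],
            index=matrix.index,
            name="mode",
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        (path / "features.txt").write_text("\n".join(self.features) + "\n")
        self.scaler.to_frame().to_csv(path / "scaler.tsv", sep="\t", index=False)
        self.booster.save_model(path / "model.json")
        (path / "manifest.json").write_text(
            json.dumps({"hyperparams": self.hyperparams, **self.manifest}, indent=2, sort_keys=True)
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrophicModelBundle":
        path = Path(path)
        for fname in ("features.txt", "scaler.tsv", "model.json", "manifest.json"):
            if not (path / fname).exists():
                raise FileNotFoundError(f"corrupt model bundle: missing {fname} in {path}")
        features = (path / "features.txt").read_text().split()
        scaler = ScalerParams.from_frame(pd.read_csv(path / "scaler.tsv", sep="\t"))
        booster = Booster()
        booster.load_model(str(path / "model.json"))
        manifest = json.loads((path / "manifest.json").read_text())
        return cls(
            features=features,
            scaler=scaler,
            booster=booster,
            hyperparams=manifest.get("hyperparams", {}),
            manifest={k: v for k, v in manifest.items() if k != "hyperparams"},
        )


def train_bundle(
    matrix: pd.DataFrame,
    labels: pd.Series,
    features: list[str] | None = None,
    params: Mapping | None = None,
    seed: int = 0,
) -> TrophicModelBundle:
    """Fit the final classifier on the full training set and package it.

    ``features`` restricts the model to a selected Pfam list (zero-filling
    any missing column); the min/max scaler is fitted on the restricted
    training matrix and travels with the bundle.
    """
    feats = list(features) if features is not None else list(matrix.columns)
    X = matrix.reindex(columns=feats, fill_value=0.0)
    scaler = fit_scaler(X)
    Xs = apply_scaler(X, scaler)
    y = encode_labels(labels)
    hp = dict(DEFAULT_HYPERPARAMS)
    if params:
        hp.update(params)
    clf = make_classifier(hp, seed=_sub_seed(seed, "final_fit"))
    clf.fit(Xs.to_numpy(dtype=float), y)
    booster = clf.get_booster()
    counts = pd.Series([canonical_mode(l) for l in labels]).value_counts().to_dict()
    digest = hashlib.sha256(
        pd.util.hash_pandas_object(Xs, index=True).to_numpy().tobytes()
    ).hexdigest()
    manifest = {
        "n_profiles": int(len(matrix)),
        "label_counts": {m: int(counts.get(m, 0)) for m in MODES},
        "seed": int(seed),
        "training_matrix_sha256": digest,
    }
    return TrophicModelBundle(
        features=feats, scaler=scaler, booster=booster, hyperparams=hp, manifest=manifest
    )
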