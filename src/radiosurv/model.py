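"""Multivariate survival classification.

Censored survival times are imputed so every patient can enter a binary
short- vs long-survival classification; outcome labels come from a median
split of the (imputed) overall survival; a 500-tree random forest is
evaluated by stratified 10-fold cross-validated AUC and by an independent
train/test split; feature relevance is measured by out-of-bag permutation
importance normalized by its tree-level standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .stats import SurvivalRecord, logrank_test, median_split

__all__ = [
    "FeatureTable",
    "OutcomeLabels",
    "ModelResult",
    "impute_censored",
    "make_outcome",
    "crossval_auc",
    "train_test_eval",
    "oob_permutation_importance",
    "integrate_blocks",
    "transcriptome_screen",
]

BLOCK_NAMES = ("radiomic", "clinical", "genomic", "transcriptomic", "protein")


@dataclass
class FeatureTable:
    """Patients × features with a block tag per column.

    ``data`` is indexed by patient id; ``blocks`` maps every column name to
    exactly one of radiomic / clinical / genomic / transcriptomic / protein.
    """

    data: pd.DataFrame
    blocks: dict[str, str]

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate patient ids")
        missing = set(self.data.columns) - set(self.blocks)
        if missing:
            raise ValueError(f"columns without a block tag: {sorted(missing)}")
        bad = set(self.blocks.values()) - set(BLOCK_NAMES)
        if bad:
            raise ValueError(f"unknown block tags: {sorted(bad)}")
        if self.data.isna().any().any():
            raise ValueError("feature table contains missing values")

    @property
    def n_patients(self) -> int:
        return len(self.data)

    def columns_of(self, block: str) -> list[str]:
        return [c for c in self.data.columns if self.blocks[c] == block]


@dataclass
class OutcomeLabels:
    labels: np.ndarray  # 0 = short-term, 1 = long-term survivor
    cutoff_days: float

    def __post_init__(self) -> None:
        u = set(np.unique(self.labels))
        if u != {0, 1}:
            raise ValueError("both outcome classes must be nonempty")


@dataclass
class ModelResult:
    fold_aucs: np.ndarray
    mean_auc: float
    out_of_fold_scores: np.ndarray
    predicted_groups: np.ndarray
    importances: pd.Series | None
    seed: int
    pooled_auc: float | None = None
    extras: dict = field(default_factory=dict)


def impute_censored(records: list[SurvivalRecord]) -> np.ndarray:
    """Replace each censored time by the mean survival of uncensored
    patients who lived at least as long.

    A censored time beyond every observed death keeps its own value (the
    rule has no donor set there). Uncensored times pass through unchanged.
    """
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    if events.sum() == 0:
        raise ValueError("cannot impute: no uncensored record")
    uncensored = times[events == 1]
    out = times.copy()
    for i in np.where(events == 0)[0]:
        donors = uncensored[uncensored >= times[i]]
        if donors.size:
            out[i] = donors.mean()
    return out


def make_outcome(records: list[SurvivalRecord]) -> OutcomeLabels:
    """Median split of imputed overall survival: label 1 = survival at or
    above the median (long-term)."""
    imputed = impute_censored(records)
    labels = median_split(imputed)
    return OutcomeLabels(labels=labels, cutoff_days=float(np.median(imputed)))


def _fit_forest(X, y, n_trees, seed) -> RandomForestClassifier:
    rf = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, bootstrap=True, n_jobs=1
    )
    rf.fit(X, y)
    return rf


def oob_permutation_importance(
    forest: RandomForestClassifier,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-feature permutation importance from out-of-bag observations.

    For every tree, the increase in OOB misclassification error after
    permuting one feature is recorded; the per-feature mean over trees is
    divided by the per-feature standard deviation of those tree-level
    increases (trees where the feature is unused contribute zero increase).
    Positive values mark predictive features; values near zero or negative
    mark non-predictive ones.
    """
    n_samples, n_features = X.shape
    n_trees = len(forest.estimators_)
    increases = np.zeros((n_trees, n_features))
    for t, (tree, sampled) in enumerate(
        zip(forest.estimators_, forest.estimators_samples_)
    ):
        oob = np.setdiff1d(np.arange(n_samples), sampled)
        if oob.size == 0:
            continue
        Xo = X[oob]
        yo = y[oob]
        base_err = np.mean(tree.predict(Xo) != yo)
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        for f in used:
            Xp = Xo.copy()
            Xp[:, f] = Xo[rng.permutation(oob.size), f]
            increases[t, f] = np.mean(tree.predict(Xp) != yo) - base_err
    mean_inc = increases.mean(axis=0)
    std_inc = increases.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(std_inc > 0, mean_inc / std_inc, 0.0)
    return norm


def crossval_auc(
    table: FeatureTable,
    labels: OutcomeLabels,
    n_trees: int = 500,
    k: int = 10,
    seed: int = 0,
    compute_importance: bool = False,
) -> ModelResult:
    """Stratified k-fold cross-validated AUC of a random forest.

    The headline metric is the mean AUC across folds; out-of-fold class-1
    probabilities (one per patient) are kept, with predicted groups at the
    0.5 threshold, and a pooled-prediction AUC is reported alongside. With
    ``compute_importance`` the normalized OOB permutation importance is
    averaged across the fold models.
    """
    X = table.data.to_numpy(dtype=float)
    y = np.asarray(labels.labels, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(f"need at least k={k} patients per class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.full(len(y), np.nan)
    fold_aucs = []
    importances = np.zeros(X.shape[1]) if compute_importance else None
    rng = np.random.default_rng(seed)
    for f, (tr, te) in enumerate(skf.split(X, y)):
        rf = _fit_forest(X[tr], y[tr], n_trees, seed * 1000 + f)
        scores = rf.predict_proba(X[te])[:, 1]
        oof[te] = scores
        fold_aucs.append(roc_auc_score(y[te], scores))
        if compute_importance:
            importances += oob_permutation_importance(rf, X[tr], y[tr], rng)
    fold_aucs = np.array(fold_aucs)
    imp = (
        pd.Series(importances / k, index=table.data.columns)
        if compute_importance
        else None
    )
    return ModelResult(
        fold_aucs=fold_aucs,
        mean_auc=float(fold_aucs.mean()),
        out_of_fold_scores=oof,
        predicted_groups=(oof >= 0.5).astype(int),
        importances=imp,
        seed=seed,
        pooled_auc=float(roc_auc_score(y, oof)),
    )


def train_test_eval(
    table: FeatureTable,
    labels: OutcomeLabels,
    records: list[SurvivalRecord] | None = None,
    test_size: float | int = 0.5,
    n_trees: int = 500,
    seed: int = 0,
    compute_importance: bool = False,
) -> ModelResult:
    """Random train/test split evaluation (e.g. 100/100 on a 200-patient
    cohort): fit on the training half only, report AUC, predicted
    short/long groups and (optionally) the log-rank comparison of the
    predicted groups on the held-out half."""
    X = table.data.to_numpy(dtype=float)
    y = np.asarray(labels.labels, dtype=int)
    idx = np.arange(len(y))
    tr, te = train_test_split(
        idx, test_size=test_size, random_state=seed, stratify=y
    )
    rf = _fit_forest(X[tr], y[tr], n_trees, seed)
    scores = rf.predict_proba(X[te])[:, 1]
    auc = float(roc_auc_score(y[te], scores))
    pred = (scores >= 0.5).astype(int)
    extras: dict = {
        "train_ids": table.data.index[tr].tolist(),
        "test_ids": table.data.index[te].tolist(),
    }
    if records is not None and len(set(pred)) == 2:
        lr = logrank_test(
            [records[i] for i, p in zip(te, pred) if p == 0],
            [records[i] for i, p in zip(te, pred) if p == 1],
        )
        extras["logrank_p"] = lr.p_value
        extras["logrank_statistic"] = lr.statistic
    imp = None
    if compute_importance:
        rng = np.random.default_rng(seed)
        imp = pd.Series(
            oob_permutation_importance(rf, X[tr], y[tr], rng),
            index=table.data.columns,
        )
    oof = np.full(len(y), np.nan)
    oof[te] = scores
    return ModelResult(
        fold_aucs=np.array([auc]),
        mean_auc=auc,
        out_of_fold_scores=oof,
        predicted_groups=(oof >= 0.5).astype(int),
        importances=imp,
        seed=seed,
        extras=extras,
    )


def integrate_blocks(
    radiomics: pd.DataFrame | None = None,
    clinical: pd.DataFrame | None = None,
    genomics: pd.DataFrame | None = None,
    transcriptomics: pd.DataFrame | None = None,
    proteins: pd.DataFrame | None = None,
    include: tuple[str, ...] | None = None,
) -> FeatureTable:
    """Column-wise concatenation of the requested feature blocks.

    Clinical categoricals (sex, therapy_type) become indicator columns.
    Patients missing any requested block are dropped (inner join on ids).
    """
    provided = {
        "radiomic": radiomics,
        "clinical": clinical,
        "genomic": genomics,
        "transcriptomic": transcriptomics,
        "protein": proteins,
    }
    if include is None:
        include = tuple(b for b, df in provided.items() if df is not None)
    frames = []
    blocks: dict[str, str] = {}
    for block in include:
        df = provided.get(block)
        if df is None:
            raise ValueError(f"block '{block}' requested but not provided")
        df = df.copy()
        if block == "clinical":
            cat_cols = [c for c in df.columns if df[c].dtype == object]
            if cat_cols:
                df = pd.get_dummies(df, columns=cat_cols, dtype=float)
        for c in df.columns:
            if c in blocks:
                raise ValueError(f"duplicate column '{c}' across blocks")
            blocks[c] = block
        frames.append(df)
    if not frames:
        raise ValueError("no blocks to integrate")
    joined = pd.concat(frames, axis=1, join="inner")
    if joined.empty:
        raise ValueError("no patients shared across the requested blocks")
    joined = joined.dropna()
    return FeatureTable(joined.astype(float), blocks)


def transcriptome_screen(
    expression: pd.DataFrame,
    records: list[SurvivalRecord],
    alpha: float = 0.05,
) -> list[str]:
    """Per-gene median-split log-rank screen.

    Genes whose raw (uncorrected) log-rank p-value is below ``alpha`` are
    retained as the prognostic transcriptomic panel. An empty selection is
    a valid result (the block is simply absent downstream).
    """
    selected = []
    for gene in expression.columns:
        vals = expression[gene].to_numpy(dtype=float)
        try:
            labels = median_split(vals)
        except ValueError:
            continue
        lr = logrank_test(
            [r for r, g in zip(records, labels) if g == 0],
            [r for r, g in zip(records, labels) if g == 1],
        )
        if lr.p_value < alpha:
            selected.append(gene)
    return selected
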