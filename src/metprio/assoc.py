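"""Disease-metabolite pair classification and candidate ranking.

Positive examples are the known (focal disease, metabolite) associations;
negatives are sampled without replacement from one of two pools:

* SP mode — metabolites associated with some *other* disease but not the
  focal one (harder negatives);
* SM mode — metabolites with no known disease association at all.

Each pair's feature vector combines the focal disease's reduced features
with the metabolite's (concatenation by default, element-wise product
optionally).  An RBF-kernel SVM supplies a continuous decision score per
pair; stratified k-fold cross-validation with per-fold standardization
(fitted on training folds only, to avoid leakage) yields per-fold and
pooled AUC/AUPR, and a final model trained on all pairs ranks every
unlabeled metabolite against the focal disease.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._errors import DataError
from .reduce import ReducedFeatures

MODES = ("SP", "SM")


@dataclass
class AssociationSet:
    """Known disease-metabolite associations plus the optional no-disease
    metabolite list used for SM-mode negatives."""

    pairs: set[tuple[str, str]]
    focal_disease: str
    no_disease_metabolites: set[str] | None = None

    def __post_init__(self):
        self.pairs = {(str(d), str(m)) for d, m in self.pairs}

    @property
    def focal_positives(self) -> set[str]:
        """Metabolites associated with the focal disease."""
        return {m for d, m in self.pairs if d == self.focal_disease}

    @property
    def other_associated(self) -> set[str]:
        """Metabolites associated with at least one non-focal disease."""
        return {m for d, m in self.pairs if d != self.focal_disease}

    def sp_negative_pool(self) -> set[str]:
        """Metabolites tied to other diseases but not to the focal one."""
        return self.other_associated - self.focal_positives

    def sm_negative_pool(self) -> set[str]:
        if self.no_disease_metabolites is None:
            raise DataError(
                "SM mode requires a no-disease metabolite list"
            )
        return set(self.no_disease_metabolites) - self.focal_positives


@dataclass
class PairDataset:
    disease_ids: list[str]
    metabolite_ids: list[str]
    X: np.ndarray
    y: np.ndarray
    mode: str
    seed: int

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=int)
        if not set(np.unique(self.y)) <= {0, 1}:
            raise DataError("pair labels must be binary")
        if len({(d, m) for d, m in zip(self.disease_ids, self.metabolite_ids)}) != len(self.y):
            raise DataError("duplicate disease-metabolite pairs in dataset")

    @property
    def n_pairs(self) -> int:
        return len(self.y)


@dataclass
class EvaluationReport:
    fold_auc: list[float]
    fold_aupr: list[float]
    pooled_auc: float
    pooled_aupr: float
    roc_points: np.ndarray      # columns fpr, tpr
    pr_points: np.ndarray       # columns recall, precision
    k: int
    seed: int
    mode: str = ""

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def mean_aupr(self) -> float:
        return float(np.mean(self.fold_aupr))

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "k": self.k,
            "seed": self.seed,
            "fold_auc": [float(a) for a in self.fold_auc],
            "fold_aupr": [float(a) for a in self.fold_aupr],
            "mean_auc": self.mean_auc,
            "mean_aupr": self.mean_aupr,
            "pooled_auc": float(self.pooled_auc),
            "pooled_aupr": float(self.pooled_aupr),
        }


def combine_features(dis_vec: np.ndarray, met_vec: np.ndarray,
                     how: str = "concat") -> np.ndarray:
    if how == "concat":
        return np.concatenate([dis_vec, met_vec])
    if how == "product":
        if dis_vec.shape != met_vec.shape:
            raise DataError(
                "element-wise product needs equal disease/metabolite dims"
            )
        return dis_vec * met_vec
    raise DataError(f"unknown feature combination {how!r}")


def make_pairs(
    assoc: AssociationSet,
    dis_feat: ReducedFeatures,
    met_feat: ReducedFeatures,
    mode: str = "SP",
    ratio: float = 1.0,
    seed: int = 0,
    combine: str = "concat",
) -> PairDataset:
    """Labeled (focal disease, metabolite) pairs with sampled negatives.

    Positives are every known focal association with a feature row;
    ``ratio * n_positives`` negatives are drawn without replacement from the
    mode's pool (sorted ids, seeded generator, so the draw is reproducible).
    """
    if mode not in MODES:
        raise DataError(f"mode must be one of {MODES}, got {mode!r}")
    focal = assoc.focal_disease
    dis_vec = dis_feat.row(focal)

    positives = sorted(assoc.focal_positives)
    if not positives:
        raise DataError(f"no known associations for focal disease {focal!r}")
    missing = [m for m in positives if m not in met_feat.node_ids]
    if missing:
        raise DataError(f"positive metabolite(s) lack feature rows: {missing[:5]}")

    pool = sorted(
        (assoc.sp_negative_pool() if mode == "SP" else assoc.sm_negative_pool())
        & set(met_feat.node_ids)
    )
    n_neg = int(round(ratio * len(positives)))
    if len(pool) < n_neg:
        raise DataError(
            f"{mode} negative pool has {len(pool)} metabolites; "
            f"{n_neg} negatives requested"
        )
    rng = np.random.default_rng(seed)
    negatives = sorted(rng.choice(pool, size=n_neg, replace=False).tolist())

    mets = positives + negatives
    labels = np.array([1] * len(positives) + [0] * len(negatives))
    X = np.vstack([combine_features(dis_vec, met_feat.row(m), combine) for m in mets])
    return PairDataset(
        disease_ids=[focal] * len(mets),
        metabolite_ids=mets,
        X=X,
        y=labels,
        mode=mode,
        seed=seed,
    )


class PairSVM(BaseEstimator, ClassifierMixin):
    """Standardize-then-SVC classifier exposing continuous decision scores.

    RBF kernel with gamma = 1 / (n_features * feature variance) ("scale")
    and C = 1 by default; scores come from the SVM margin, no probability
    calibration.  Deterministic given the data and its order.
    """

    def __init__(self, C: float = 1.0, kernel: str = "rbf",
                 gamma: str | float = "scale", scale_features: bool = True):
        self.C = C
        self.kernel = kernel
        self.gamma = gamma
        self.scale_features = scale_features

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise DataError("cannot train SVM on single-class data")
        steps = []
        if self.scale_features:
            steps.append(StandardScaler())
        steps.append(SVC(C=self.C, kernel=self.kernel, gamma=self.gamma))
        self.pipeline_ = make_pipeline(*steps)
        self.pipeline_.fit(X, y)
        self.classes_ = self.pipeline_.steps[-1][1].classes_
        return self

    def decision_function(self, X) -> np.ndarray:
        if not hasattr(self, "pipeline_"):
            raise DataError("PairSVM is not fitted")
        return self.pipeline_.decision_function(np.asarray(X, dtype=float))

    def predict(self, X) -> np.ndarray:
        return self.pipeline_.predict(np.asarray(X, dtype=float))


def train_svm(ds: PairDataset, svm_config: dict | None = None) -> PairSVM:
    """Fit the pair classifier on the whole dataset."""
    model = PairSVM(**(svm_config or {}))
    return model.fit(ds.X, ds.y)


def compute_metrics(y_true, scores) -> tuple[float, float]:
    """(AUC, AUPR) of continuous scores against binary labels."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise DataError("metrics need both classes present")
    return (
        float(roc_auc_score(y_true, scores)),
        float(average_precision_score(y_true, scores)),
    )


def cross_validate(
    ds: PairDataset,
    k: int = 10,
    seed: int = 0,
    classifier: BaseEstimator | None = None,
) -> EvaluationReport:
    """Stratified k-fold evaluation of held-out decision scores.

    Per-fold AUC/AUPR plus pooled metrics over the concatenated held-out
    scores (the headline numbers); ROC and PR curves are computed on the
    pooled scores.  Feature standardization happens inside the per-fold
    classifier, fitted on the training folds only.
    """
    if k < 2:
        raise DataError(f"k must be >= 2, got {k}")
    minority = int(min(np.sum(ds.y == 1), np.sum(ds.y == 0)))
    if minority == 0:
        raise DataError("cross-validation needs both classes")
    if k > minority:
        raise DataError(
            f"k={k} exceeds minority class count {minority}; "
            "each stratified fold must contain both classes"
        )
    base = classifier if classifier is not None else PairSVM()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_auc, fold_aupr = [], []
    pooled_scores = np.empty(ds.n_pairs)
    seen = np.zeros(ds.n_pairs, dtype=bool)
    for train_idx, test_idx in skf.split(ds.X, ds.y):
        model = clone(base)
        model.fit(ds.X[train_idx], ds.y[train_idx])
        scores = np.asarray(model.decision_function(ds.X[test_idx]), dtype=float)
        pooled_scores[test_idx] = scores
        seen[test_idx] = True
        auc, aupr = compute_metrics(ds.y[test_idx], scores)
        fold_auc.append(auc)
        fold_aupr.append(aupr)
    assert seen.all(), "folds failed to partition the dataset"
    pooled_auc, pooled_aupr = compute_metrics(ds.y, pooled_scores)
    fpr, tpr, _ = roc_curve(ds.y, pooled_scores)
    precision, recall, _ = precision_recall_curve(ds.y, pooled_scores)
    return EvaluationReport(
        fold_auc=fold_auc,
        fold_aupr=fold_aupr,
        pooled_auc=pooled_auc,
        pooled_aupr=pooled_aupr,
        roc_points=np.column_stack([fpr, tpr]),
        pr_points=np.column_stack([recall, precision]),
        k=k,
        seed=seed,
        mode=ds.mode,
    )


def rank_candidates(
    model: PairSVM,
    dis_feat: ReducedFeatures,
    met_feat: ReducedFeatures,
    focal: str,
    exclude: set[str],
    combine: str = "concat",
    threshold: float = 0.0,
) -> list[tuple[str, float, bool]]:
    """Score every non-excluded metabolite against the focal disease.

    Returns (metabolite_id, decision_score, predicted_associated) sorted by
    descending score, ties broken by metabolite id.  ``predicted_associated``
    marks scores above the SVM margin (``threshold``, default 0).
    """
    dis_vec = dis_feat.row(focal)
    candidates = sorted(set(met_feat.node_ids) - set(exclude))
    if not candidates:
        raise DataError("candidate set is empty after exclusions")
    X = np.vstack([combine_features(dis_vec, met_feat.row(m), combine)
                   for m in candidates])
    scores = model.decision_function(X)
    order = sorted(range(len(candidates)),
                   key=lambda i: (-scores[i], candidates[i]))
    return [(candidates[i], float(scores[i]), bool(scores[i] > threshold))
            for i in order]


# ---------------------------------------------------------------------------
# external interfaces

def read_association_list(path, focal: str,
                          no_disease_path=None) -> AssociationSet:
    """2-column TSV (disease_id, metabolite_id) with header; optional
    one-id-per-line no-disease metabolite file."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise DataError(f"association list needs 2 columns, got {df.shape[1]}")
    pairs = {(str(d), str(m)) for d, m in df.iloc[:, :2].itertuples(index=False)}
    no_disease = None
    if no_disease_path is not None:
        with open(no_disease_path) as fh:
            no_disease = {line.strip() for line in fh if line.strip()}
    return AssociationSet(pairs, focal, no_disease)


def write_report(report: EvaluationReport, json_path,
                 roc_path=None, pr_path=None) -> None:
    with open(json_path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    if roc_path is not None:
        pd.DataFrame(report.roc_points, columns=["fpr", "tpr"]).to_csv(
            roc_path, sep="\t", index=False, float_format="%.12g")
    if pr_path is not None:
        pd.DataFrame(report.pr_points, columns=["recall", "precision"]).to_csv(
            pr_path, sep="\t", index=False, float_format="%.12g")


def write_ranking(ranking: list[tuple[str, float, bool]], path) -> None:
    pd.DataFrame(ranking, columns=["metabolite_id", "score", "predicted_associated"]
                 ).to_csv(path, sep="\t", index=False, float_format="%.12g")
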