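"""7-class glomerulopathy subtype classification.

Feature fusion + selection + stacking ensemble over the subtype vocabulary
(MCD, MN, IgA, LN, DN, MsPGN, TBMN):

* statistical features are the per-image measurement results (GBM thickness
  statistics, shape/skeleton quality statistics, foot-process density and
  effacement grade, deposit presence/burden);
* an optional fixed-length embedding block from a pluggable hook (default: a
  classical 32-dim descriptor of mask-boundary orientations and
  thickness-profile quantiles) is concatenated to the statistical block;
* L1-penalized (LASSO) multinomial logistic regression selects the features
  with any nonzero coefficient at a cross-validated regularization weight;
* a stacking classifier with 4 base learners of distinct families (RBF
  support vector machine, extreme gradient boosting, k-nearest neighbors,
  light gradient boosting machine) feeds a linear meta-model fitted on the
  out-of-fold stacked class probabilities (one-vs-rest least squares,
  clipped at zero and renormalized to the simplex).

All randomness (fold assignment, base-learner seeds) derives from one
integer seed stored in the model.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .ultrastructure_scoring import FusionGrade

logger = logging.getLogger(__name__)

#: Statistical feature schema, fixed order.
STAT_FEATURES = (
    "thickness_mean_nm",
    "thickness_sd_nm",
    "thickness_min_nm",
    "thickness_max_nm",
    "compactness_mean",
    "compactness_sd",
    "fill_rate_mean",
    "fill_rate_sd",
    "norm_curvature_mean",
    "norm_curvature_sd",
    "norm_branch_mean",
    "gbm_count",
    "gbm_total_length_um",
    "fp_count",
    "fp_density_per_um",
    "effacement_fraction",
    "grade_no_fusion",
    "grade_segmental",
    "grade_extensive",
    "grade_diffuse",
    "diffuse_flag",
    "edd_present",
    "edd_count",
    "edd_area_um2",
)

MISSING_FLAGS = ("gbm_missing", "fp_missing", "edd_missing")

EMBEDDING_DIM = 32


def default_embedding(record: dict, instances=None) -> np.ndarray:
    """Classical 32-dim embedding: boundary-orientation histogram (16 bins
    over [0, π)) of accepted GBM contours + 16 quantiles of the pooled
    boundary thickness profile (normalized by its median).

    A stand-in feature hook with the same two-block fusion interface a deep
    image encoder would use; it sees only mask geometry, never intensities.
    """
    orient = np.zeros(16)
    samples = []
    for inst in instances or []:
        if not getattr(inst, "accepted", False):
            continue
        if inst.contour is not None and len(inst.contour) > 2:
            d = np.diff(inst.contour, axis=0)
            ang = np.arctan2(d[:, 0], d[:, 1]) % np.pi
            w = np.linalg.norm(d, axis=1)
            h, _ = np.histogram(ang, bins=16, range=(0, np.pi), weights=w)
            orient += h
        if inst.thickness is not None and inst.thickness.distances_px.size:
            samples.append(inst.thickness.distances_px)
    if orient.sum() > 0:
        orient = orient / orient.sum()
    if samples:
        pooled = np.concatenate(samples)
        q = np.quantile(pooled, np.linspace(0.05, 0.95, 16))
        q = q / (np.median(pooled) + 1e-12)
    else:
        q = np.zeros(16)
    return np.concatenate([orient, q])


def assemble_features(
    record: dict,
    *,
    instances=None,
    embedding: np.ndarray | None = None,
    use_embedding: bool = True,
) -> pd.Series:
    """Build one named feature vector from a per-image measurement record.

    Missing blocks (no accepted GBM, no FP measurement) produce NaNs plus a
    raised missing-flag; NaNs are imputed later with training-set medians.
    """
    vals: dict[str, float] = {}
    gbm_ok = bool(record.get("gbm_measured"))
    fp_ok = bool(record.get("fp_measured"))
    insts = [i for i in (instances or []) if getattr(i, "accepted", False)]

    def stat(vector, fn, default=np.nan):
        return float(fn(vector)) if len(vector) else default

    comp = [i.descriptors.compactness for i in insts if i.descriptors]
    fill = [i.descriptors.fill_rate for i in insts if i.descriptors]
    kap = [i.skeleton.norm_curvature for i in insts if i.skeleton]
    bra = [i.skeleton.norm_branch for i in insts if i.skeleton]
    vals["thickness_mean_nm"] = record.get("thickness_mean_nm", np.nan) if gbm_ok else np.nan
    vals["thickness_sd_nm"] = record.get("thickness_sd_nm", np.nan) if gbm_ok else np.nan
    vals["thickness_min_nm"] = record.get("thickness_min_nm", np.nan) if gbm_ok else np.nan
    vals["thickness_max_nm"] = record.get("thickness_max_nm", np.nan) if gbm_ok else np.nan
    vals["compactness_mean"] = stat(comp, np.mean)
    vals["compactness_sd"] = stat(comp, np.std, 0.0)
    vals["fill_rate_mean"] = stat(fill, np.mean)
    vals["fill_rate_sd"] = stat(fill, np.std, 0.0)
    vals["norm_curvature_mean"] = stat(kap, np.mean)
    vals["norm_curvature_sd"] = stat(kap, np.std, 0.0)
    vals["norm_branch_mean"] = stat(bra, np.mean)
    vals["gbm_count"] = record.get("gbm_count", 0)
    vals["gbm_total_length_um"] = record.get("total_skeleton_len_nm", 0.0) / 1000.0
    vals["fp_count"] = record.get("fp_count", 0) if fp_ok else np.nan
    vals["fp_density_per_um"] = record.get("fp_density_per_um", np.nan) if fp_ok else np.nan
    vals["effacement_fraction"] = record.get("effacement_fraction", np.nan) if fp_ok else np.nan
    grade = record.get("fusion_grade")
    for g in FusionGrade:
        vals[f"grade_{g.value}"] = float(grade == g.value) if fp_ok else np.nan
    vals["diffuse_flag"] = float(bool(record.get("diffuse_flag")))
    vals["edd_present"] = float(bool(record.get("edd_present")))
    vals["edd_count"] = record.get("edd_count", 0)
    vals["edd_area_um2"] = record.get("edd_area_nm2", 0.0) / 1e6
    vals["gbm_missing"] = float(not gbm_ok)
    vals["fp_missing"] = float(not fp_ok)
    vals["edd_missing"] = 0.0
    if use_embedding:
        emb = embedding if embedding is not None else default_embedding(record, instances)
        emb = np.asarray(emb, dtype=float)
        if emb.shape != (EMBEDDING_DIM,):
            raise ValueError(f"embedding must have length {EMBEDDING_DIM}, got {emb.shape}")
        for j, v in enumerate(emb):
            vals[f"emb_{j:02d}"] = float(v)
    return pd.Series(vals)


def feature_matrix(rows: list[pd.Series]) -> pd.DataFrame:
    X = pd.DataFrame(rows).reset_index(drop=True)
    return X


# ---------------------------------------------------------------------------
# LASSO feature selection
# ---------------------------------------------------------------------------

@dataclass
class SelectedFeatures:
    names: list[str]
    coef: np.ndarray  # (n_classes, n_features) at the chosen penalty
    c_chosen: float
    fallback_all: bool = False


def lasso_select(
    X: pd.DataFrame,
    y: np.ndarray,
    *,
    c_grid: np.ndarray | None = None,
    folds: int = 5,
    seed: int = 0,
) -> SelectedFeatures:
    """Cross-validated L1 multinomial logistic feature selection.

    Columns are standardized internally; features with any nonzero
    coefficient at the deviance-optimal penalty are retained.  Constant
    columns are dropped with a warning.  If the optimal penalty empties the
    support, all features are retained (with a warning) so downstream
    training can proceed.
    """
    if len(np.unique(y)) < 2:
        raise ValueError("feature selection needs at least 2 classes")
    keep = [c for c in X.columns if np.nanstd(X[c].to_numpy(dtype=float)) > 1e-12]
    dropped = set(X.columns) - set(keep)
    if dropped:
        logger.warning("dropping constant columns: %s", sorted(dropped))
    Xk = X[keep].to_numpy(dtype=float)
    med = np.nanmedian(Xk, axis=0)
    Xk = np.where(np.isnan(Xk), med, Xk)
    if c_grid is None:
        c_grid = np.logspace(-3, 2, 11)
    c_grid = np.sort(np.asarray(c_grid, dtype=float))
    folds = min(folds, int(np.min(np.bincount(pd.factorize(y)[0]))))
    folds = max(folds, 2)
    skf = StratifiedKFold(folds, shuffle=True, random_state=seed)
    Xs = StandardScaler().fit_transform(Xk)

    def _lr(C):
        return LogisticRegression(solver="saga", l1_ratio=1.0, C=C,
                                  max_iter=5000, tol=1e-3, random_state=seed)

    means, ses = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for C in c_grid:
            s = cross_val_score(_lr(C), Xs, y, cv=skf, scoring="accuracy")
            means.append(s.mean())
            ses.append(s.std(ddof=1) / np.sqrt(len(s)))
        # one-standard-error rule on CV misclassification: sparsest penalty
        # whose mean score is within 1 SE of the best
        means = np.asarray(means)
        best = int(np.argmax(means))
        cutoff = means[best] - ses[best]
        chosen = c_grid[int(np.argmax(means >= cutoff))]
        final = _lr(chosen).fit(Xs, y)
    coef = final.coef_
    support = np.any(np.abs(coef) > 1e-8, axis=0)
    names = [keep[i] for i in range(len(keep)) if support[i]]
    fallback = False
    if not names:
        logger.warning("LASSO emptied the support; retaining all features")
        names, fallback = list(keep), True
    return SelectedFeatures(
        names=names,
        coef=coef[:, support] if not fallback else coef,
        c_chosen=float(chosen),
        fallback_all=fallback,
    )


# ---------------------------------------------------------------------------
# stacking classifier
# ---------------------------------------------------------------------------

def _default_bases(seed: int) -> list[tuple[str, object]]:
    from lightgbm import LGBMClassifier
    from xgboost import XGBClassifier

    return [
        ("svm", make_pipeline(StandardScaler(), SVC(probability=True, random_state=seed))),
        ("xgb", XGBClassifier(
            n_estimators=200, max_depth=3, learning_rate=0.1, subsample=0.9,
            random_state=seed, verbosity=0, eval_metric="mlogloss",
        )),
        ("knn", make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=5))),
        ("lgbm", LGBMClassifier(
            n_estimators=200, max_depth=-1, learning_rate=0.1,
            random_state=seed, verbose=-1,
        )),
    ]


@dataclass
class StackingModel:
    """4 base learners + linear meta-model over stacked class probabilities."""

    classes: list[str]
    feature_names: list[str]
    impute_medians: np.ndarray
    base_models: list = field(default_factory=list)
    base_names: list[str] = field(default_factory=list)
    meta_weights: np.ndarray | None = None  # (n_classes, 4*n_classes + 1)
    seed: int = 0
    folds: int = 5

    def _prepare(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in X.columns]
        if missing:
            raise ValueError(f"input lacks selected features: {missing}")
        A = X[self.feature_names].to_numpy(dtype=float)
        return np.where(np.isnan(A), self.impute_medians, A)

    def _stack(self, A: np.ndarray) -> np.ndarray:
        probs = [m.predict_proba(A) for m in self.base_models]
        Z = np.hstack(probs)
        return np.hstack([Z, np.ones((len(Z), 1))])

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        A = self._prepare(X)
        scores = self._stack(A) @ self.meta_weights.T
        scores = np.clip(scores, 0.0, None)
        rs = scores.sum(axis=1, keepdims=True)
        uniform = np.full_like(scores, 1.0 / scores.shape[1])
        return np.where(rs > 0, scores / np.where(rs == 0, 1, rs), uniform)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        p = self.predict_proba(X)
        return np.asarray(self.classes)[np.argmax(p, axis=1)]


def train_stacking(
    X: pd.DataFrame,
    y: np.ndarray,
    *,
    folds: int = 5,
    seed: int = 0,
    classes: list[str] | None = None,
) -> StackingModel:
    """Fit the stacking ensemble with out-of-fold base probabilities.

    Base learners produce k-fold out-of-fold class probabilities; the meta
    linear model is one-vs-rest least squares on the stacked probabilities
    (scores clipped at 0 and renormalized at predict time); base learners
    are then refitted on all data.
    """
    classes = list(classes) if classes is not None else sorted(set(map(str, y)))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    y = np.asarray([str(v) for v in y])
    y_idx = np.array([classes.index(v) for v in y])
    counts = np.bincount(y_idx, minlength=len(classes))
    min_count = counts[counts > 0].min()
    if min_count < folds:
        logger.warning("reducing folds %d -> %d (smallest class)", folds, max(int(min_count), 2))
        folds = max(int(min_count), 2)

    A = X.to_numpy(dtype=float)
    med = np.nanmedian(A, axis=0)
    A = np.where(np.isnan(A), med, A)

    skf = StratifiedKFold(folds, shuffle=True, random_state=seed)
    bases = _default_bases(seed)
    oof = []
    for name, model in bases:
        p = cross_val_predict(model, A, y_idx, cv=skf, method="predict_proba", n_jobs=1)
        if p.shape[1] != len(classes):  # class absent in training data
            full = np.zeros((len(A), len(classes)))
            present = sorted(set(y_idx))
            full[:, present] = p
            p = full
        oof.append(p)
    Z = np.hstack(oof)
    Z1 = np.hstack([Z, np.ones((len(Z), 1))])
    Y = np.zeros((len(y_idx), len(classes)))
    Y[np.arange(len(y_idx)), y_idx] = 1.0
    W, *_ = np.linalg.lstsq(Z1, Y, rcond=None)

    fitted = []
    for name, model in bases:
        model.fit(A, y_idx)
        fitted.append(model)
    return StackingModel(
        classes=classes,
        feature_names=list(X.columns),
        impute_medians=med,
        base_models=fitted,
        base_names=[n for n, _ in bases],
        meta_weights=W.T,
        seed=seed,
        folds=folds,
    )


def predict_subtype(model: StackingModel, x: pd.Series | pd.DataFrame) -> dict:
    """Probability simplex over the model's class vocabulary for one image."""
    X = x.to_frame().T if isinstance(x, pd.Series) else x
    p = model.predict_proba(X)[0]
    order = np.argsort(-p)
    return {
        "probabilities": {c: float(p[i]) for i, c in enumerate(model.classes)},
        "top1": model.classes[order[0]],
        "top3": [model.classes[i] for i in order[:3]],
    }


def pool_patient_probability(probas: np.ndarray) -> np.ndarray:
    """Patient-level probability: mean over the patient's per-image rows."""
    probas = np.atleast_2d(np.asarray(probas, dtype=float))
    if probas.size == 0:
        raise ValueError("empty probability set")
    p = probas.mean(axis=0)
    return p / p.sum()


def topk_accuracy(proba: np.ndarray, labels: np.ndarray, classes: list[str], k: int) -> float:
    """Fraction of samples whose true label is among the k most probable."""
    if len(labels) == 0:
        raise ValueError("empty input")
    proba = np.asarray(proba)
    idx = np.argsort(-proba, axis=1)[:, :k]
    lab_idx = np.array([classes.index(str(v)) for v in labels])
    return float(np.mean([lab_idx[i] in idx[i] for i in range(len(lab_idx))]))


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(model: StackingModel, path: str | Path) -> None:
    """Serialize the model: JSON manifest + joblib sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": 1,
        "classes": model.classes,
        "feature_names": model.feature_names,
        "base_names": model.base_names,
        "seed": model.seed,
        "folds": model.folds,
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))
    joblib.dump(model, path.with_suffix(".joblib"))


def load_model(path: str | Path) -> StackingModel:
    path = Path(path)
    model = joblib.load(path.with_suffix(".joblib"))
    manifest = json.loads(path.with_suffix(".json").read_text())
    if manifest["classes"] != model.classes:
        raise ValueError("model manifest does not match sidecar")
    return model
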