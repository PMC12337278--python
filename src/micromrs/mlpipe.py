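"""Leakage-controlled LOOCV classification: standardize -> SMOTE -> PCA -> SVM.

Every fold refits the scaler, the minority oversampler and the PCA on the
training rows only; the held-out sample is transformed with the fold's frozen
parameters and never participates in fitting, and synthetic (SMOTE) rows never
reach a validation fold. Held-out decision scores are pooled across folds into
one confusion matrix and one rank-based ROC AUC.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "PipelineConfig",
    "FoldModel",
    "CVResult",
    "MetricsReport",
    "smote",
    "fit_fold",
    "predict_fold",
    "loocv",
    "metrics",
    "dummy_baseline",
    "rank_auc",
    "pca_scatter_data",
    "pca_loadings",
]

POSITIVE_LABELS = ("DEV", "MAT")  # developmental-competence / maturation classes


@dataclass
class PipelineConfig:
    """Hyperparameters of the per-fold pipeline.

    ``pca_components=None`` keeps all train-rank components (the top 8 are what
    get reported downstream). ``pca_before_smote`` switches the PCA/SMOTE order;
    the default oversamples first, then rotates.
    """

    smote_k: int = 5
    pca_components: int | float | None = None
    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"
    class_weight: str | dict | None = None
    pca_before_smote: bool = False
    positive_label: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.kernel not in ("rbf", "linear"):
            raise ValueError("kernel must be 'rbf' or 'linear'")
        if self.smote_k < 1:
            raise ValueError("smote_k must be >= 1")


def _feature_columns(table: pd.DataFrame) -> list[str]:
    drop = {"sample_id", "label", "snr", "linewidth_ppm"}
    return [c for c in table.columns if c not in drop]


def _positive_label(labels: Sequence[str], cfg: PipelineConfig) -> str:
    classes = sorted(set(labels))
    if cfg.positive_label is not None:
        if cfg.positive_label not in classes:
            raise ValueError(f"positive label {cfg.positive_label!r} not in {classes}")
        return cfg.positive_label
    for lbl in POSITIVE_LABELS:
        if lbl in classes:
            return lbl
    # fall back to the minority class
    counts = {c: list(labels).count(c) for c in classes}
    return min(classes, key=lambda c: (counts[c], c))


# ---------------------------------------------------------------------------
# SMOTE


def smote(
    minority: np.ndarray, k: int, n_new: int, rng: np.random.Generator
) -> np.ndarray:
    """Interpolated minority oversampling in (already standardized) space.

    Each synthetic row is x + u*(x' - x) with u ~ U(0,1), x a random minority
    row and x' one of its k nearest minority neighbours (Euclidean). With a
    single minority row no interpolation is possible: the row is duplicated
    with a warning.
    """
    minority = np.asarray(minority, dtype=float)
    if n_new == 0:
        return np.empty((0, minority.shape[1]))
    if minority.shape[0] == 1:
        warnings.warn("single minority sample: SMOTE duplicates it", stacklevel=2)
        return np.repeat(minority, n_new, axis=0)
    k_eff = min(k, minority.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(minority)
    _, idx = nn.kneighbors(minority)  # column 0 is the point itself
    base = rng.integers(0, minority.shape[0], size=n_new)
    pick = rng.integers(1, k_eff + 1, size=n_new)
    u = rng.uniform(0.0, 1.0, size=(n_new, 1))
    x = minority[base]
    x_nb = minority[idx[base, pick]]
    return x + u * (x_nb - x)


def _balance(X: np.ndarray, y: np.ndarray, k: int, rng: np.random.Generator):
    """SMOTE the minority class up to the majority count; returns augmented
    arrays plus a mask flagging synthetic rows."""
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("training fold must contain exactly two classes")
    minority_cls = classes[np.argmin(counts)]
    n_new = int(counts.max() - counts.min())
    if n_new == 0:
        return X, y, np.zeros(len(y), dtype=bool)
    synth = smote(X[y == minority_cls], k, n_new, rng)
    X_aug = np.vstack([X, synth])
    y_aug = np.concatenate([y, np.full(n_new, minority_cls, dtype=y.dtype)])
    synthetic = np.concatenate([np.zeros(len(y), bool), np.ones(n_new, bool)])
    return X_aug, y_aug, synthetic


# ---------------------------------------------------------------------------
# fold model


@dataclass
class FoldModel:
    scaler: StandardScaler
    pca: PCA
    svm: SVC
    positive_label: str
    pca_before_smote: bool
    n_train: int
    n_synthetic: int

    def transform(self, rows: np.ndarray) -> np.ndarray:
        z = self.scaler.transform(np.atleast_2d(rows))
        return self.pca.transform(z)

    def params_digest(self) -> str:
        """Hash of all fitted parameters; equality means identical fold fits."""
        h = hashlib.sha256()
        for arr in (self.scaler.mean_, self.scaler.scale_, self.pca.components_,
                    self.pca.mean_, self.svm.dual_coef_, self.svm.support_vectors_,
                    np.atleast_1d(self.svm.intercept_)):
            h.update(np.ascontiguousarray(arr, dtype=float).tobytes())
        return h.hexdigest()


def fit_fold(
    X_train: np.ndarray, y_train: np.ndarray, cfg: PipelineConfig,
    rng: np.random.Generator | None = None,
) -> FoldModel:
    """Fit scaler -> SMOTE -> PCA -> SVM (or PCA before SMOTE) on one fold."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    if np.unique(y_train).size < 2:
        raise ValueError("training fold contains a single class")
    scaler = StandardScaler().fit(X_train)
    Z = scaler.transform(X_train)

    if cfg.pca_before_smote:
        pca = _fit_pca(Z, cfg)
        P = pca.transform(Z)
        P_bal, y_bal, synth = _balance(P, y_train, cfg.smote_k, rng)
        scores = P_bal
    else:
        Z_bal, y_bal, synth = _balance(Z, y_train, cfg.smote_k, rng)
        pca = _fit_pca(Z_bal, cfg)
        scores = pca.transform(Z_bal)

    svm = SVC(kernel=cfg.kernel, C=cfg.C, gamma=cfg.gamma,
              class_weight=cfg.class_weight)
    svm.fit(scores, y_bal)
    return FoldModel(
        scaler=scaler, pca=pca, svm=svm,
        positive_label=_positive_label(list(y_train), cfg),
        pca_before_smote=cfg.pca_before_smote,
        n_train=len(y_train), n_synthetic=int(synth.sum()),
    )


def _fit_pca(Z: np.ndarray, cfg: PipelineConfig) -> PCA:
    n_comp = cfg.pca_components
    max_rank = min(Z.shape)
    if n_comp is None:
        n_comp = max_rank
    elif isinstance(n_comp, int):
        n_comp = min(n_comp, max_rank)
    return PCA(n_components=n_comp, svd_solver="full").fit(Z)


def predict_fold(model: FoldModel, row: np.ndarray) -> tuple[str, float]:
    """Transform with the fold's frozen parameters and score; never refits.

    The score is the signed SVM margin oriented so that larger means more
    likely the positive (DEV/MAT) class.
    """
    scores = model.transform(row)
    raw = float(model.svm.decision_function(scores)[0])
    # sklearn orients decision_function toward classes_[1]
    sign = 1.0 if model.svm.classes_[1] == model.positive_label else -1.0
    margin = sign * raw
    label = model.positive_label if margin > 0 else next(
        c for c in model.svm.classes_ if c != model.positive_label)
    return str(label), margin


# ---------------------------------------------------------------------------
# LOOCV


@dataclass
class CVResult:
    sample_ids: list[str]
    y_true: list[str]
    y_pred: list[str]
    scores: list[float]
    positive_label: str
    fold_digests: list[str] = field(default_factory=list)


def _fold_seed(master_seed: int, held_out_id: str) -> int:
    digest = hashlib.sha256(f"{master_seed}:{held_out_id}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


def loocv(table: pd.DataFrame, cfg: PipelineConfig) -> CVResult:
    """Leave-one-out CV with fold-local seeds keyed on the held-out sample id,
    so per-sample predictions are invariant to row order."""
    if len(table) < 4:
        raise ValueError("LOOCV needs at least 4 samples")
    labels = table["label"].to_numpy()
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    if counts.min() < 2:
        raise ValueError(
            "minority class has a single member: every fold holding it out "
            "would train on one class"
        )
    feats = _feature_columns(table)
    X = table[feats].to_numpy(float)
    ids = table["sample_id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise ValueError("sample_id values must be unique")
    pos = _positive_label(labels, cfg)

    res = CVResult([], [], [], [], positive_label=pos)
    # canonical (id-sorted) training order: SMOTE neighbor draws then depend
    # only on the fold's membership, never on the table's row order
    order = np.argsort(np.asarray(ids))
    for i, sid in enumerate(ids):
        train_idx = order[order != i]
        X_tr = _impute_train_median(X[train_idx])
        rng = np.random.default_rng(_fold_seed(cfg.seed, sid))
        model = fit_fold(X_tr.imputed, labels[train_idx], cfg, rng)
        row = X_tr.fill_row(X[i])
        pred, score = predict_fold(model, row)
        res.sample_ids.append(sid)
        res.y_true.append(str(labels[i]))
        res.y_pred.append(pred)
        res.scores.append(score)
        res.fold_digests.append(model.params_digest())
    return res


@dataclass
class _ImputedTrain:
    imputed: np.ndarray
    medians: np.ndarray

    def fill_row(self, row: np.ndarray) -> np.ndarray:
        row = row.astype(float).copy()
        bad = ~np.isfinite(row)
        row[bad] = self.medians[bad]
        return row


def _impute_train_median(X: np.ndarray) -> _ImputedTrain:
    """Train-fold median imputation of non-finite entries (e.g. failed
    Lorentzian fits); the held-out row is filled with the *train* medians."""
    X = X.astype(float).copy()
    med = np.nanmedian(np.where(np.isfinite(X), X, np.nan), axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    bad = ~np.isfinite(X)
    X[bad] = np.broadcast_to(med, X.shape)[bad]
    return _ImputedTrain(imputed=X, medians=med)


# ---------------------------------------------------------------------------
# metrics


@dataclass
class MetricsReport:
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    npv: float
    f1: float
    auc: float
    positive_label: str
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "tp", "fp", "fn", "tn", "accuracy", "balanced_accuracy",
            "sensitivity", "specificity", "precision", "npv", "f1", "auc",
            "positive_label")}


def rank_auc(y_true_binary: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC via the Mann-Whitney rank formulation with tie midranks."""
    y = np.asarray(y_true_binary, bool)
    s = np.asarray(scores, float)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = stats.rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _safe_div(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return float("nan")
    return num / den


def metrics(cv: CVResult) -> MetricsReport:
    """Pooled confusion-matrix panel over the held-out predictions."""
    pos = cv.positive_label
    y = np.asarray(cv.y_true)
    p = np.asarray(cv.y_pred)
    if not ((y == pos).any() and (y != pos).any()):
        raise ValueError("need both classes among true labels")
    tp = int(np.sum((y == pos) & (p == pos)))
    fn = int(np.sum((y == pos) & (p != pos)))
    fp = int(np.sum((y != pos) & (p == pos)))
    tn = int(np.sum((y != pos) & (p != pos)))
    undefined: list[str] = []
    sens = _safe_div(tp, tp + fn, "sensitivity", undefined)
    spec = _safe_div(tn, tn + fp, "specificity", undefined)
    prec = _safe_div(tp, tp + fp, "precision", undefined)
    npv = _safe_div(tn, tn + fn, "npv", undefined)
    if np.isnan(prec) or np.isnan(sens) or (prec + sens) == 0:
        undefined.append("f1")
        f1 = float("nan")
    else:
        f1 = 2 * prec * sens / (prec + sens)
    auc = rank_auc(y == pos, np.asarray(cv.scores))
    return MetricsReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        accuracy=(tp + tn) / len(y),
        balanced_accuracy=(sens + spec) / 2.0,
        sensitivity=sens, specificity=spec, precision=prec, npv=npv, f1=f1,
        auc=auc, positive_label=pos, undefined=tuple(undefined),
    )


def dummy_baseline(table: pd.DataFrame, cfg: PipelineConfig | None = None) -> MetricsReport:
    """Majority-class constant predictor; constant scores force AUC = 0.5."""
    cfg = cfg or PipelineConfig()
    labels = table["label"].astype(str).tolist()
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    majority = max(classes, key=lambda c: (labels.count(c), c))
    cv = CVResult(
        sample_ids=table["sample_id"].astype(str).tolist(),
        y_true=labels,
        y_pred=[majority] * len(labels),
        scores=[0.0] * len(labels),
        positive_label=_positive_label(labels, cfg),
    )
    return metrics(cv)


# ---------------------------------------------------------------------------
# whole-dataset PCA views (explicitly non-inferential exploratory scatter and
# loadings data, where SMOTE/PCA run on the full standardized table)


def _sign_fix(pca: PCA) -> PCA:
    comp = pca.components_
    for i in range(comp.shape[0]):
        j = int(np.argmax(np.abs(comp[i])))
        if comp[i, j] < 0:
            comp[i] *= -1.0
    pca.components_ = comp
    return pca


def fit_whole_dataset_view(table: pd.DataFrame, cfg: PipelineConfig | None = None):
    """Standardize the whole table, SMOTE-balance it, fit PCA. Returns
    ``(scores, labels, synthetic_mask, pca, feature_names)``."""
    cfg = cfg or PipelineConfig()
    feats = _feature_columns(table)
    X = _impute_train_median(table[feats].to_numpy(float)).imputed
    y = table["label"].to_numpy()
    scaler = StandardScaler().fit(X)
    Z = scaler.transform(X)
    rng = np.random.default_rng(cfg.seed)
    Z_bal, y_bal, synth = _balance(Z, y, cfg.smote_k, rng)
    if min(Z_bal.shape) < 2:
        raise ValueError("rank < 2: cannot compute a PC1-PC2 view")
    pca = _sign_fix(_fit_pca(Z_bal, cfg))
    return pca.transform(Z_bal), y_bal, synth, pca, feats


def pca_scatter_data(table: pd.DataFrame, cfg: PipelineConfig | None = None):
    """(PC1, PC2) scores, labels and a synthetic-row mask for plotting."""
    scores, y_bal, synth, _, _ = fit_whole_dataset_view(table, cfg)
    return scores[:, 0], scores[:, 1], y_bal, synth


def pca_loadings(table: pd.DataFrame, cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Loading matrix (features x PCs), deterministic sign convention."""
    _, _, _, pca, feats = fit_whole_dataset_view(table, cfg)
    cols = [f"PC{i+1}" for i in range(pca.components_.shape[0])]
    return pd.DataFrame(pca.components_.T, index=feats, columns=cols)
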