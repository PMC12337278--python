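"""Exact Shapley attribution over principal-component features.

With at most ~14 PC features, the Shapley value of each feature can be
computed exactly by enumerating all 2^n coalitions against an interventional
value function: v(S) is the background-mean model score with the features in S
taken from the explained sample and the rest from the background row. The
efficiency, symmetry, linearity and null-player axioms then hold to numerical
precision, with no sampling approximation to reason about.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial
from typing import Callable

import numpy as np
import pandas as pd

from .mlpipe import (
    PipelineConfig,
    _balance,
    _feature_columns,
    _fit_pca,
    _impute_train_median,
)
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = ["exact_shapley", "ShapleyReport", "shap_summary"]

MAX_FEATURES = 16


def exact_shapley(
    score_fn: Callable[[np.ndarray], np.ndarray],
    background_rows: np.ndarray,
    x: np.ndarray,
    n_features: int | None = None,
) -> tuple[np.ndarray, float]:
    """Exact interventional Shapley values of ``score_fn`` at ``x``.

    Returns ``(phi, base_value)`` where ``base_value`` is the mean background
    score and ``base_value + phi.sum()`` equals ``score_fn(x)`` exactly
    (efficiency). ``score_fn`` must accept a 2-D array and return one score
    per row.
    """
    bg = np.atleast_2d(np.asarray(background_rows, dtype=float))
    x = np.asarray(x, dtype=float).ravel()
    n = x.size if n_features is None else n_features
    if n != x.size:
        raise ValueError("n_features must match len(x)")
    if n > MAX_FEATURES:
        raise ValueError(
            f"{n} features would need 2^{n} coalition evaluations; "
            f"exact enumeration is limited to {MAX_FEATURES}"
        )
    if bg.shape[0] == 0:
        raise ValueError("background_rows must be nonempty")
    n_coal = 1 << n
    b = bg.shape[0]
    # batch all coalition x background evaluations into one score_fn call
    masks = ((np.arange(n_coal)[:, None] >> np.arange(n)) & 1).astype(bool)
    rows = np.where(masks[:, None, :], x[None, None, :], bg[None, :, :])
    v = score_fn(rows.reshape(n_coal * b, n)).reshape(n_coal, b).mean(axis=1)

    sizes = masks.sum(axis=1)
    fact = np.array([factorial(k) for k in range(n + 1)], dtype=float)
    phi = np.zeros(n)
    for i in range(n):
        has_i = masks[:, i]
        without = np.flatnonzero(~has_i)
        s = sizes[without]
        weight = fact[s] * fact[n - s - 1] / fact[n]
        phi[i] = float(np.sum(weight * (v[without | (1 << i)] - v[without])))
    base = float(v[0])
    return phi, base


@dataclass
class ShapleyReport:
    values: pd.DataFrame        # samples x PC features
    base_value: float
    scores: np.ndarray          # model score per explained sample
    ranking: list[str]          # features ordered by mean |phi|
    loadings: pd.DataFrame      # biomarkers x PCs of the explained model's PCA

    def top(self, k: int = 8) -> pd.DataFrame:
        """Mean |phi| of the k most influential features (bar-plot data)."""
        mean_abs = self.values.abs().mean(axis=0)
        return mean_abs.loc[self.ranking[:k]].to_frame("mean_abs_shap")

    def dominant_biomarker(self, pc: str | None = None) -> str:
        """Biomarker with the largest |loading| on a PC (default: top-ranked)."""
        pc = pc or self.ranking[0]
        return str(self.loadings[pc].abs().idxmax())


def _refit_full(table: pd.DataFrame, cfg: PipelineConfig):
    """Refit scaler -> SMOTE -> PCA -> SVM on the full dataset (the model the
    attribution explains). Rows are fit in id-sorted order so
    the result is invariant to the table's row order."""
    table = table.sort_values("sample_id", kind="stable").reset_index(drop=True)
    feats = _feature_columns(table)
    X = _impute_train_median(table[feats].to_numpy(float)).imputed
    y = table["label"].to_numpy()
    rng = np.random.default_rng(cfg.seed)
    scaler = StandardScaler().fit(X)
    Z = scaler.transform(X)
    if cfg.pca_before_smote:
        pca = _fit_pca(Z, cfg)
        P_bal, y_bal, _ = _balance(pca.transform(Z), y, cfg.smote_k, rng)
        train_scores = P_bal
    else:
        Z_bal, y_bal, _ = _balance(Z, y, cfg.smote_k, rng)
        pca = _fit_pca(Z_bal, cfg)
        train_scores = pca.transform(Z_bal)
    svm = SVC(kernel=cfg.kernel, C=cfg.C, gamma=cfg.gamma,
              class_weight=cfg.class_weight).fit(train_scores, y_bal)
    pc_scores_real = pca.transform(Z)  # original (non-synthetic) samples only
    loadings = pd.DataFrame(
        pca.components_.T, index=feats,
        columns=[f"PC{i+1}" for i in range(pca.components_.shape[0])],
    )
    return svm, pc_scores_real, loadings


def shap_summary(
    table: pd.DataFrame,
    cfg: PipelineConfig | None = None,
    top_k: int = 8,
    background_size: int | None = 16,
    model_and_scores=None,
) -> ShapleyReport:
    """Per-sample exact Shapley values on PC features of a full-data refit.

    ``background_size`` subsamples the background set (seeded) to bound the
    2^n x background cost; ``None`` uses every sample. Pass
    ``model_and_scores=(svm, pc_scores)`` to explain an existing fit instead.
    """
    cfg = cfg or PipelineConfig()
    table = table.sort_values("sample_id", kind="stable").reset_index(drop=True)
    if model_and_scores is None:
        svm, pc_scores, loadings = _refit_full(table, cfg)
    else:
        svm, pc_scores = model_and_scores[:2]
        loadings = (model_and_scores[2] if len(model_and_scores) > 2 else
                    pd.DataFrame(np.eye(pc_scores.shape[1]),
                                 columns=[f"PC{j+1}" for j in range(pc_scores.shape[1])],
                                 index=[f"PC{j+1}" for j in range(pc_scores.shape[1])]))
    n_feat = pc_scores.shape[1]
    if n_feat > MAX_FEATURES:
        raise ValueError(f"{n_feat} PC features exceed the exact-enumeration limit")
    bg = pc_scores
    if background_size is not None and background_size < bg.shape[0]:
        rng = np.random.default_rng(cfg.seed)
        bg = bg[rng.choice(bg.shape[0], size=background_size, replace=False)]

    def score_fn(rows: np.ndarray) -> np.ndarray:
        return svm.decision_function(rows)

    phis = np.empty_like(pc_scores)
    base = 0.0
    for i in range(pc_scores.shape[0]):
        phis[i], base = exact_shapley(score_fn, bg, pc_scores[i])
    cols = [f"PC{j+1}" for j in range(n_feat)]
    values = pd.DataFrame(phis, columns=cols, index=table["sample_id"].astype(str))
    ranking = values.abs().mean(axis=0).sort_values(ascending=False).index.tolist()
    return ShapleyReport(
        values=values, base_value=base,
        scores=svm.decision_function(pc_scores), ranking=ranking,
        loadings=loadings,
    )
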