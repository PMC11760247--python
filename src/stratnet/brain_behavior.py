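"""Edge-wise brain-behavior association and cross-validated prediction.

Two layers:

* :func:`edgewise_association` — mass-univariate partial Pearson correlation
  between every edge's FC and one symptom, after residualizing both on the
  covariates; two-sided p from the t transform with df = n - 2 - n_covariates.
* :func:`predict_symptom_cv` — connectome-based predictive modeling (CPM):
  per fold, select edges at alpha on training subjects, split by sign, sum
  FC into a (positive - negative) network strength, fit a one-dimensional
  linear map strength -> symptom, and predict held-out subjects.  All
  predictions are out-of-fold.

Plus the observed-vs-brain-predicted symptom similarity comparison with a
subject-level swap permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from ._regression import design_matrix, orthonormal_basis, residualize

logger = logging.getLogger(__name__)


@dataclass
class EdgePredictionMap:
    """Per-edge association of one (condition, symptom) pair."""

    condition: str
    symptom: str
    alpha: float
    r: np.ndarray
    p: np.ndarray
    selected: np.ndarray
    sign: np.ndarray  # +1/-1 on selected edges, 0 elsewhere
    zero_variance: np.ndarray
    n: int
    n_covariates: int

    @property
    def n_edges(self) -> int:
        return self.r.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "edge_id": [f"e{k + 1}" for k in range(self.n_edges)],
                "r": self.r,
                "p": self.p,
                "selected": self.selected,
                "sign": self.sign,
            }
        )


def _partial_r_matrix(
    x_resid: np.ndarray, y_resid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of residualized y against every residualized column of x.

    Returns (r, zero_variance mask).  Zero-variance columns get r = 0.
    """
    xn = np.linalg.norm(x_resid, axis=0)
    yn = np.linalg.norm(y_resid)
    scale = np.sqrt(x_resid.shape[0])
    zero_var = xn <= 1e-12 * scale
    if yn <= 1e-12 * scale:
        raise ValueError("symptom has zero residual variance")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x_resid.T @ y_resid) / (xn * yn)
    r[zero_var] = 0.0
    return np.clip(r, -1.0, 1.0), zero_var


def _p_from_r(r: np.ndarray, df: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    return 2.0 * stats.t.sf(np.abs(t), df)


def edgewise_association(
    connectome: np.ndarray,
    symptom: np.ndarray,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    *,
    condition: str = "",
    symptom_name: str = "",
    fdr: bool = False,
) -> EdgePredictionMap:
    """Partial correlation of every edge with one symptom.

    Edges with zero variance are flagged and assigned r = 0, p = 1.  With
    ``fdr=True`` selection uses Benjamini-Hochberg adjusted p-values at
    ``alpha`` instead of raw ones.  Selection is inclusive (p <= alpha).
    """
    x = np.asarray(connectome, dtype=float)
    y = np.asarray(symptom, dtype=float).ravel()
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("connectome and symptom must share subject ordering")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    n = x.shape[0]
    design, n_cov = design_matrix(covariates, n)
    if n <= n_cov + 3:
        raise ValueError(
            f"n_subjects = {n} too small for {n_cov} covariates (need > n_cov + 3)"
        )
    basis = orthonormal_basis(design)
    x_resid = residualize(x, basis)
    y_resid = residualize(y, basis)
    r, zero_var = _partial_r_matrix(x_resid, y_resid)
    df = n - 2 - n_cov
    p = _p_from_r(r, df)
    p[zero_var] = 1.0
    if fdr:
        from .stats import bh_fdr

        selected = bh_fdr(p) <= alpha
    else:
        selected = p <= alpha
    sign = np.where(selected, np.sign(r).astype(np.int8), np.int8(0))
    return EdgePredictionMap(
        condition=condition,
        symptom=symptom_name,
        alpha=alpha,
        r=r,
        p=p,
        selected=selected,
        sign=sign,
        zero_variance=zero_var,
        n=n,
        n_covariates=n_cov,
    )


@dataclass
class PredictedSymptoms:
    """Out-of-fold CPM predictions for one (condition-set, symptom)."""

    symptom: str
    predicted: np.ndarray
    observed: np.ndarray
    fold_of: np.ndarray
    k_folds: int
    seed: int
    n_selected_per_fold: list[int] = field(default_factory=list)


def predict_symptom_cv(
    connectome: np.ndarray,
    symptom: np.ndarray,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    k_folds: int = 10,
    seed: int = 0,
    *,
    symptom_name: str = "",
) -> PredictedSymptoms:
    """CPM with k-fold cross-validation; returns out-of-fold predictions.

    Edge selection and network strength use covariate-residualized FC (the
    residualization is fit on training subjects only); the strength ->
    symptom map is fit on the raw training symptom, so predictions are on
    the symptom's original scale.  Folds selecting zero edges fall back to
    the training mean (logged).
    """
    x = np.asarray(connectome, dtype=float)
    y = np.asarray(symptom, dtype=float).ravel()
    n = x.shape[0]
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if x.shape[0] != y.shape[0]:
        raise ValueError("connectome and symptom must share subject ordering")
    # dummy-code once over all subjects so folds share one design layout
    design_all, n_cov = design_matrix(covariates, n)

    predicted = np.empty(n)
    fold_of = np.empty(n, dtype=int)
    n_selected = []
    splitter = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    for fold, (train, test) in enumerate(splitter.split(x)):
        design_tr = design_all[train]
        coef, *_ = np.linalg.lstsq(design_tr, np.column_stack([x[train], y[train]]), rcond=None)
        resid_tr = np.column_stack([x[train], y[train]]) - design_tr @ coef
        x_tr, y_tr = resid_tr[:, :-1], resid_tr[:, -1]
        r, zero_var = _partial_r_matrix(x_tr, y_tr)
        p = _p_from_r(r, len(train) - 2 - n_cov)
        p[zero_var] = 1.0
        sel = p <= alpha
        pos = sel & (r > 0)
        neg = sel & (r < 0)
        n_selected.append(int(sel.sum()))

        x_te = x[test] - design_all[test] @ coef[:, :-1]
        if not sel.any():
            logger.warning(
                "CPM fold %d selected zero edges for %r; predicting training mean",
                fold,
                symptom_name,
            )
            predicted[test] = y[train].mean()
        else:
            strength_tr = x_tr[:, pos].sum(axis=1) - x_tr[:, neg].sum(axis=1)
            strength_te = x_te[:, pos].sum(axis=1) - x_te[:, neg].sum(axis=1)
            slope, intercept = np.polyfit(strength_tr, y[train], 1)
            predicted[test] = slope * strength_te + intercept
        fold_of[test] = fold

    return PredictedSymptoms(
        symptom=symptom_name,
        predicted=predicted,
        observed=y,
        fold_of=fold_of,
        k_folds=k_folds,
        seed=seed,
        n_selected_per_fold=n_selected,
    )


# ---------------------------------------------------------------------------
# similarity of observed vs brain-predicted symptom profiles
# ---------------------------------------------------------------------------

def similarity_matrices(
    observed: pd.DataFrame | np.ndarray, predicted: pd.DataFrame | np.ndarray
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrices of observed and predicted symptoms."""
    obs = pd.DataFrame(observed)
    pred = pd.DataFrame(predicted)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must share subjects and symptoms")
    pred.columns = obs.columns
    for name, df in [("observed", obs), ("predicted", pred)]:
        if (df.std(axis=0, ddof=0) <= 0).any():
            bad = df.columns[df.std(axis=0, ddof=0) <= 0].tolist()
            raise ValueError(f"zero-variance {name} symptom(s): {bad}")
    return obs.corr(), pred.corr()


def _within_domain_pairs(domain_labels) -> list[tuple[int, int]]:
    labels = list(domain_labels)
    counts: dict[str, int] = {}
    for d in labels:
        counts[d] = counts.get(d, 0) + 1
    small = [d for d, c in counts.items() if c < 2]
    if small:
        raise ValueError(f"domains with < 2 symptoms: {small}")
    return [
        (i, j)
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
        if labels[i] == labels[j]
    ]


def _r_mean(mat: np.ndarray, pairs: list[tuple[int, int]]) -> float:
    corr = np.corrcoef(mat, rowvar=False)
    return float(np.mean([corr[i, j] for i, j in pairs]))


@dataclass
class SimilarityComparison:
    r_mean_obs: float
    r_mean_pred: float
    difference: float
    p_perm: float
    n_perm: int


def compare_mean_similarity(
    observed: pd.DataFrame | np.ndarray,
    predicted: pd.DataFrame | np.ndarray,
    domain_labels,
    n_perm: int = 1000,
    seed: int = 0,
) -> SimilarityComparison:
    """Is the brain-predicted within-domain similarity higher than observed?

    ``r_mean`` is the mean off-diagonal within-domain correlation (pooled
    over domains).  The null is built by swapping, independently per subject
    and per symptom, whether the observed or predicted value enters each
    matrix, then recomputing the difference in ``r_mean``; p uses the
    add-one convention, one-sided for predicted > observed.
    """
    obs = pd.DataFrame(observed).to_numpy(dtype=float)
    pred = pd.DataFrame(predicted).to_numpy(dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must share subjects and symptoms")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    pairs = _within_domain_pairs(domain_labels)
    diff = _r_mean(pred, pairs) - _r_mean(obs, pairs)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        mask = rng.random(obs.shape) < 0.5
        a = np.where(mask, pred, obs)
        b = np.where(mask, obs, pred)
        if _r_mean(a, pairs) - _r_mean(b, pairs) >= diff:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return SimilarityComparison(
        r_mean_obs=_r_mean(obs, pairs),
        r_mean_pred=_r_mean(pred, pairs),
        difference=diff,
        p_perm=p,
        n_perm=n_perm,
    )
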