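"""Statistic conversions and group-comparison machinery.

The closed-form identities used to report effect sizes alongside test
statistics:

* ``r = t / sqrt(t^2 + n - 2)`` (Pearson correlation from its t statistic),
* two-sample ``d = t * sqrt(1/n1 + 1/n2)`` (pooled-variance convention),
* one-sample ``d = t / sqrt(n)``.

Plus pooled/Welch case-control comparison of factor scores with optional
covariate residualization, application of a fixed edge set to an external
cohort (task or resting-state mode), and Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

from ._regression import design_matrix, orthonormal_basis, residualize
from .factors import CrossDisorderEdgeSet


def r_from_t(t: float, n: int) -> float:
    """Pearson r implied by a correlation t statistic with n subjects."""
    if n < 3:
        raise ValueError("n must be >= 3")
    return float(t / np.sqrt(t**2 + n - 2))


def t_from_r(r: float, n: int) -> float:
    """Inverse of :func:`r_from_t`."""
    if n < 3:
        raise ValueError("n must be >= 3")
    if not -1.0 < r < 1.0:
        raise ValueError("r must lie strictly inside (-1, 1)")
    return float(r * np.sqrt((n - 2) / (1.0 - r**2)))


def cohens_d_two_sample_from_t(t: float, n1: int, n2: int) -> float:
    """Two-sample Cohen's d from a pooled-variance t statistic."""
    if n1 < 2 or n2 < 2:
        raise ValueError("both group sizes must be >= 2")
    return float(t * np.sqrt(1.0 / n1 + 1.0 / n2))


def cohens_d_one_sample_from_t(t: float, n: int) -> float:
    """One-sample Cohen's d (mean/SD) from its t statistic."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return float(t / np.sqrt(n))


@dataclass
class GroupComparison:
    """A case-control contrast of per-subject scores."""

    n_case: int
    n_control: int
    t_stat: float
    cohens_d: float
    p: float
    tail: str
    direction: str


def group_compare(
    scores: np.ndarray | pd.Series,
    labels: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
    tail: str = "two",
    direction: str = "greater",
    welch: bool = False,
) -> GroupComparison:
    """Case-vs-control comparison of factor scores.

    ``labels`` is boolean (or 0/1) with True = case.  Scores are first
    residualized on the covariates when given.  The default is the pooled
    two-sample t, whose d identity ``d = t * sqrt(1/n1 + 1/n2)`` holds
    exactly; Welch is available by flag.  With ``tail='one'`` the p-value
    is one-sided in the declared ``direction`` ('greater': case > control).
    """
    y = np.asarray(scores, dtype=float).ravel()
    lab = np.asarray(labels).astype(bool).ravel()
    if y.shape != lab.shape:
        raise ValueError("scores and labels must be aligned")
    if lab.all() or not lab.any():
        raise ValueError("both case and control groups must be present")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    if covariates is not None:
        design, _ = design_matrix(pd.DataFrame(covariates), y.size)
        y = residualize(y, orthonormal_basis(design))
    case, control = y[lab], y[~lab]
    n1, n2 = case.size, control.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 subjects per group")
    t, p_two = _stats.ttest_ind(case, control, equal_var=not welch)
    t = float(t)
    d = cohens_d_two_sample_from_t(t, n1, n2)
    if tail == "two":
        p = float(p_two)
    else:
        df = n1 + n2 - 2 if not welch else None
        if welch:
            # recompute one-sided from the Welch result
            p = float(p_two) / 2 if (t > 0) == (direction == "greater") else 1 - float(p_two) / 2
        else:
            p = float(_stats.t.sf(t, df) if direction == "greater" else _stats.t.cdf(t, df))
    return GroupComparison(
        n_case=n1, n_control=n2, t_stat=t, cohens_d=d, p=p, tail=tail, direction=direction
    )


def apply_factor_external(
    edge_set: CrossDisorderEdgeSet,
    external_connectome,
    mode: str = "task",
) -> np.ndarray:
    """Score an external cohort with a fixed edge set.

    ``mode='task'``: ``external_connectome`` maps condition -> (subjects x
    edges); members are summed per (condition, edge) exactly as in factor
    scoring.  ``mode='rest'``: a single (subjects x edges) matrix; members
    collapse to unique node-pair edges (task conditions are unavailable at
    rest), each counted once.
    """
    if mode == "task":
        by_cond: dict[str, list[int]] = {}
        for cond, e in edge_set.members:
            by_cond.setdefault(cond, []).append(e)
        missing = sorted(set(by_cond) - set(external_connectome))
        if missing:
            raise ValueError(f"edge set references absent conditions: {missing}")
        n_edges = {np.asarray(m).shape[1] for m in external_connectome.values()}
        _check_edge_range(edge_set, max(n_edges) if n_edges else 0)
        n = next(iter(external_connectome.values())).shape[0]
        out = np.zeros(n)
        for cond, edges in by_cond.items():
            out += np.asarray(external_connectome[cond], dtype=float)[:, edges].sum(axis=1)
        return out
    if mode == "rest":
        mat = np.asarray(external_connectome, dtype=float)
        _check_edge_range(edge_set, mat.shape[1])
        unique_edges = sorted({e for _, e in edge_set.members})
        return mat[:, unique_edges].sum(axis=1) if unique_edges else np.zeros(mat.shape[0])
    raise ValueError("mode must be 'task' or 'rest'")


def _check_edge_range(edge_set: CrossDisorderEdgeSet, n_edges: int) -> None:
    for cond, e in edge_set.members:
        if e >= n_edges:
            raise ValueError(
                f"edge index mismatch: member ({cond!r}, e{e + 1}) exceeds the "
                f"external connectome's {n_edges} edges"
            )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
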