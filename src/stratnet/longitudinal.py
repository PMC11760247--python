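"""Multi-wave analysis of neural factor scores.

Per-subject change is summarized by an ordinary least-squares slope of
factor score on age across available waves (with exactly two waves this is
the two-point difference quotient).  Group-level strength of decline uses a
one-sample t on the slopes with one-sample Cohen's d = mean/SD.  Slopes are
then related to baseline symptoms by covariate-adjusted partial
correlation, and factor scores at one wave to symptoms at the same or a
later wave with a one-tailed test in the factor's expected direction
(positive for externalizing, negative for internalizing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._regression import design_matrix, orthonormal_basis, residualize


@dataclass
class TrajectoryTable:
    """Per-subject slopes plus the group-level one-sample summary."""

    slopes: pd.DataFrame  # columns: slope, n_waves_present
    n_excluded: int  # subjects with < 2 waves
    mean_slope: float
    t_stat: float
    p_two_tailed: float
    cohens_d: float
    n: int


def subject_slopes(
    scores: pd.DataFrame,
    ages: pd.DataFrame,
    complete_cases: bool = False,
) -> TrajectoryTable:
    """OLS slope of score on age per subject, plus the group one-sample t.

    ``scores`` and ``ages`` are subject x wave tables with matching shape;
    missing waves are NaN.  Subjects with fewer than 2 waves (or, with
    ``complete_cases=True``, fewer than all waves) are excluded and counted.
    """
    s = pd.DataFrame(scores)
    a = pd.DataFrame(ages)
    if s.shape != a.shape:
        raise ValueError("scores and ages must share subjects and waves")
    sv = s.to_numpy(dtype=float)
    av = a.to_numpy(dtype=float)
    ok = ~(np.isnan(sv) | np.isnan(av))
    n_waves = ok.sum(axis=1)
    need = sv.shape[1] if complete_cases else 2
    keep = n_waves >= need

    # masked closed-form OLS: slope = sum w (x - xbar)(y - ybar) / sum w (x - xbar)^2
    w = ok.astype(float)
    cnt = np.maximum(w.sum(axis=1), 1.0)
    xm = np.nansum(np.where(ok, av, 0.0), axis=1) / cnt
    ym = np.nansum(np.where(ok, sv, 0.0), axis=1) / cnt
    xc = np.where(ok, av - xm[:, None], 0.0)
    yc = np.where(ok, sv - ym[:, None], 0.0)
    sxx = (xc * xc).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = (xc * yc).sum(axis=1) / sxx
    slope = np.where(keep & (sxx > 0), slope, np.nan)

    table = pd.DataFrame(
        {"slope": slope, "n_waves_present": n_waves}, index=s.index
    )
    used = table.loc[keep & np.isfinite(slope), "slope"].to_numpy()
    n = used.size
    if n >= 2 and used.std(ddof=1) > 0:
        t_stat, p = stats.ttest_1samp(used, 0.0)
        d = used.mean() / used.std(ddof=1)
    else:
        t_stat, p, d = 0.0, 1.0, 0.0
    return TrajectoryTable(
        slopes=table,
        n_excluded=int((~keep).sum()),
        mean_slope=float(used.mean()) if n else float("nan"),
        t_stat=float(t_stat),
        p_two_tailed=float(p),
        cohens_d=float(d),
        n=n,
    )


@dataclass
class AssociationResult:
    r: float
    t_stat: float
    p: float
    n: int
    df: int
    tail: str = "two"


def _partial_corr(
    x: np.ndarray,
    y: np.ndarray,
    covariates: pd.DataFrame | None,
    tail: str = "two",
    direction: str = "greater",
) -> AssociationResult:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        ok &= cov.notna().all(axis=1).to_numpy()
        cov = cov.loc[ok]
    else:
        cov = None
    x, y = x[ok], y[ok]
    n = x.size
    design, n_cov = design_matrix(cov, n)
    if n <= n_cov + 3:
        raise ValueError("too few subjects for the covariate set")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    basis = orthonormal_basis(design)
    xr = residualize(x, basis)
    yr = residualize(y, basis)
    r = float(xr @ yr / (np.linalg.norm(xr) * np.linalg.norm(yr)))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2 - n_cov
    t = r * np.sqrt(df / max(1.0 - r**2, 1e-300))
    if tail == "two":
        p = 2.0 * stats.t.sf(abs(t), df)
    elif direction == "greater":
        p = stats.t.sf(t, df)
    else:
        p = stats.t.cdf(t, df)
    return AssociationResult(r=r, t_stat=float(t), p=float(p), n=n, df=df, tail=tail)


def slope_symptom_association(
    slopes: np.ndarray | pd.Series,
    baseline_symptoms: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
) -> AssociationResult:
    """Partial correlation of baseline domain symptom with the decline slope."""
    return _partial_corr(baseline_symptoms, slopes, covariates, tail="two")


def crosswave_prediction(
    factor_scores: np.ndarray | pd.Series,
    symptoms: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
    direction: str = "greater",
) -> AssociationResult:
    """Factor score at wave i vs symptoms at wave j >= i, one-tailed.

    ``direction='greater'`` tests r > 0 (externalizing convention);
    ``'less'`` tests r < 0 (internalizing convention).
    """
    x = np.asarray(factor_scores, dtype=float).ravel()
    y = np.asarray(symptoms, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("factor scores and symptoms must be aligned")
    overlap = int((np.isfinite(x) & np.isfinite(y)).sum())
    if overlap < 10:
        raise ValueError(f"only {overlap} overlapping subjects (< 10)")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    return _partial_corr(x, y, covariates, tail="one", direction=direction)
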