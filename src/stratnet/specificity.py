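"""Multi-level neuroanatomical characterization of neural factors.

For each cross-disorder factor (general/NP, externalizing, internalizing)
the region degree counts how many of its (condition, edge) members touch a
region; the same node pair under two task conditions contributes twice.
Degrees are normalized as ``raw / sum(raw) + 1`` — each value falls in
[1, 2] and the "+1" keeps later ratios away from singularities.  The
Specificity Score of factor F1 at a unit is ``norm(F1)/norm(F2) +
norm(F1)/norm(F3)``; the factor with the highest score is the unit's
*predominant* factor, and the *specificity distance* is the max minus min
of the three scores at that unit.

At the network level the units are network pairs (within-network pairs
included), so a parcellation with m networks yields m(m+1)/2 units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .factors import CrossDisorderEdgeSet
from .parcellation import ParcellationScheme

logger = logging.getLogger(__name__)

FACTOR_ORDER = ("NP", "externalizing", "internalizing")


def node_degree(
    edge_set: CrossDisorderEdgeSet, parcellation: ParcellationScheme
) -> np.ndarray:
    """Raw per-region degree: number of members incident to each region."""
    deg = np.zeros(parcellation.n_nodes, dtype=int)
    if not edge_set.members:
        return deg
    edges = np.array([e for _, e in edge_set.members])
    i, j = parcellation.index_to_pair(edges)
    np.add.at(deg, i, 1)
    np.add.at(deg, j, 1)
    return deg


def normalize_degree(raw: np.ndarray) -> np.ndarray:
    """``raw / sum(raw) + 1``; every value in [1, 2]."""
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise ValueError("degrees must be nonnegative")
    total = raw.sum()
    if total <= 0:
        raise ValueError("empty factor: total degree is zero")
    return raw / total + 1.0


def specificity_scores(
    norm_np: np.ndarray,
    norm_ext: np.ndarray,
    norm_int: np.ndarray,
    unit_ids=None,
) -> pd.DataFrame:
    """Two-ratio Specificity Scores, predominance, and specificity distance.

    Score of factor F1 at a unit = norm(F1)/norm(F2) + norm(F1)/norm(F3).
    Ties in predominance break by fixed factor order (NP, externalizing,
    internalizing) and are logged.
    """
    norms = {
        "NP": np.asarray(norm_np, dtype=float),
        "externalizing": np.asarray(norm_ext, dtype=float),
        "internalizing": np.asarray(norm_int, dtype=float),
    }
    n = norms["NP"].shape[0]
    for name, v in norms.items():
        if v.shape != (n,):
            raise ValueError("normalized degree vectors must be aligned")
        if np.any(v < 1.0) or np.any(v > 2.0):
            raise ValueError(f"normalized degrees for {name} must lie in [1, 2]")
    scores = {}
    for f1 in FACTOR_ORDER:
        others = [f for f in FACTOR_ORDER if f != f1]
        scores[f1] = norms[f1] / norms[others[0]] + norms[f1] / norms[others[1]]
    mat = np.column_stack([scores[f] for f in FACTOR_ORDER])
    winner = mat.argmax(axis=1)  # argmax takes the first max: fixed-order ties
    ties = (mat == mat.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        logger.info("predominance ties at %d unit(s); broken by factor order", ties.sum())
    out = pd.DataFrame(
        {
            "unit_id": np.arange(n) + 1 if unit_ids is None else list(unit_ids),
            **{f"spec_{f}": scores[f] for f in FACTOR_ORDER},
            "predominant_factor": [FACTOR_ORDER[w] for w in winner],
            "spec_distance": mat.max(axis=1) - mat.min(axis=1),
        }
    )
    return out


def network_aggregate(
    edge_set: CrossDisorderEdgeSet, parcellation: ParcellationScheme
) -> np.ndarray:
    """Network x network connection counts, divided by the largest count.

    Symmetric; within-network counts sit on the diagonal.  An empty edge
    set yields an all-zero matrix (with a warning).
    """
    m = parcellation.n_networks
    counts = np.zeros((m, m), dtype=float)
    if not edge_set.members:
        logger.warning("network_aggregate: empty edge set")
        return counts
    edges = np.array([e for _, e in edge_set.members])
    i, j = parcellation.index_to_pair(edges)
    a = parcellation.network_of[i]
    b = parcellation.network_of[j]
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    np.add.at(counts, (lo, hi), 1.0)
    counts = np.triu(counts) + np.triu(counts, k=1).T
    return counts / counts.max()


def network_pair_counts(
    edge_set: CrossDisorderEdgeSet, parcellation: ParcellationScheme
) -> np.ndarray:
    """Raw member counts per network pair, vectorized over the m(m+1)/2 units."""
    m = parcellation.n_networks
    counts = np.zeros((m, m), dtype=float)
    if edge_set.members:
        edges = np.array([e for _, e in edge_set.members])
        i, j = parcellation.index_to_pair(edges)
        a, b = parcellation.network_of[i], parcellation.network_of[j]
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        np.add.at(counts, (lo, hi), 1.0)
    iu = np.triu_indices(m)
    return counts[iu]


def network_pair_labels(parcellation: ParcellationScheme) -> list[str]:
    names = parcellation.network_names
    iu, ju = np.triu_indices(parcellation.n_networks)
    return [f"{names[a]}-{names[b]}" for a, b in zip(iu, ju)]


@dataclass
class SpecificityComparison:
    """Per-factor predominance counts and tests at one level."""

    predominance_counts: dict[str, int]
    anova_f: float
    anova_p: float
    anova_df: tuple[int, int]
    pairwise_t: dict[str, tuple[float, float]]
    mean_spec_distance: float


def _compare_one_level(table: pd.DataFrame) -> SpecificityComparison:
    counts = {
        f: int((table["predominant_factor"] == f).sum()) for f in FACTOR_ORDER
    }
    groups = [
        table.loc[table["predominant_factor"] == f, f"spec_{f}"].to_numpy()
        for f in FACTOR_ORDER
    ]
    usable = [g for g in groups if len(g) >= 2]
    pooled = np.concatenate([g for g in groups if len(g)]) if any(
        len(g) for g in groups
    ) else np.array([])
    if pooled.size and np.ptp(pooled) < 1e-12:
        # degenerate: identical scores everywhere -> no between-group variance
        f_stat, p = 0.0, 1.0
        pairwise = {}
    elif len(usable) < 2:
        logger.warning("fewer than 2 units per factor; skipping tests")
        f_stat, p = float("nan"), float("nan")
        pairwise = {}
    else:
        f_stat, p = stats.f_oneway(*[g for g in groups if len(g) >= 1])
        pairwise = {}
        for a in range(len(FACTOR_ORDER)):
            for b in range(a + 1, len(FACTOR_ORDER)):
                ga, gb = groups[a], groups[b]
                if len(ga) >= 2 and len(gb) >= 2:
                    t, tp = stats.ttest_ind(ga, gb)
                    pairwise[f"{FACTOR_ORDER[a]}-vs-{FACTOR_ORDER[b]}"] = (
                        float(t),
                        float(tp),
                    )
    k = sum(len(g) >= 1 for g in groups)
    n_total = sum(len(g) for g in groups)
    return SpecificityComparison(
        predominance_counts=counts,
        anova_f=float(f_stat),
        anova_p=float(p),
        anova_df=(k - 1, n_total - k),
        pairwise_t=pairwise,
        mean_spec_distance=float(table["spec_distance"].mean()),
    )


def compare_specificity_levels(
    region_table: pd.DataFrame, network_table: pd.DataFrame
) -> dict[str, SpecificityComparison]:
    """Summaries at region and network level (the coarse-fine gradient).

    Each unit contributes its predominant factor's score to that factor's
    group; a one-way ANOVA compares the three groups, with pairwise t tests.
    """
    return {
        "region": _compare_one_level(region_table),
        "network": _compare_one_level(network_table),
    }
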