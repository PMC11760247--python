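"""Cross-disorder edge taxonomy, permutation reliability, and factor scores.

An edge (one node pair under one task condition) is classified from its
per-symptom support pattern:

* *general* — predicts at least one symptom from each domain (or sits in a
  supplied prior general-factor mask); removed first;
* *stratified-externalizing* — predicts >= 2 externalizing symptoms and no
  internalizing symptom (symmetrically for internalizing);
* everything else is not cross-disorder.

Stratified edges are then split by the uniform direction of their supporting
associations: all-positive (pos-pos), all-negative (neg-neg), or mixed
(excluded from factors).  A neural factor score is the per-subject sum of FC
over a fixed edge set; the same edge set is re-applied at later waves.

The reliability of a stratified-edge count is assessed by permuting subject
rows of the symptom table (which breaks brain-symptom coupling while
preserving the symptom inter-correlations) and re-running the full
association + classification chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._regression import design_matrix, orthonormal_basis, residualize
from .brain_behavior import EdgePredictionMap, _p_from_r
from .simulate import EXTERNALIZING_SYMPTOMS, INTERNALIZING_SYMPTOMS, SYMPTOMS

CATEGORY_GENERAL = "general"
CATEGORY_EXT = "stratified-externalizing"
CATEGORY_INT = "stratified-internalizing"
SIGN_POS = "pos-pos"
SIGN_NEG = "neg-neg"
SIGN_MIXED = "mixed"

Member = tuple[str, int]  # (condition, edge index)


@dataclass
class CrossDisorderEdgeSet:
    """A labeled set of (condition, edge) members with their support."""

    category: str
    members: list[Member]
    support: dict[Member, tuple[tuple[str, int], ...]] = field(default_factory=dict)
    sign_group: str = "any"

    @property
    def n_edges(self) -> int:
        return len(self.members)

    def member_sign_group(self, member: Member) -> str:
        signs = {s for _, s in self.support.get(member, ())}
        if signs == {1}:
            return SIGN_POS
        if signs == {-1}:
            return SIGN_NEG
        return SIGN_MIXED

    def to_frame(self, parcellation=None) -> pd.DataFrame:
        rows = []
        for cond, e in self.members:
            row = {
                "condition": cond,
                "edge_id": f"e{e + 1}",
                "category": self.category,
                "sign_group": self.member_sign_group((cond, e)),
                "supporting_symptoms": ";".join(
                    f"{s}{'+' if g > 0 else '-'}"
                    for s, g in self.support.get((cond, e), ())
                ),
            }
            if parcellation is not None:
                i, j = parcellation.index_to_pair(e)
                row["node_i"], row["node_j"] = i + 1, j + 1
            rows.append(row)
        return pd.DataFrame(
            rows,
            columns=[
                "condition",
                "edge_id",
                "node_i",
                "node_j",
                "category",
                "sign_group",
                "supporting_symptoms",
            ]
            if parcellation is not None
            else ["condition", "edge_id", "category", "sign_group", "supporting_symptoms"],
        )


@dataclass
class ConditionTaxonomy:
    condition: str
    general: CrossDisorderEdgeSet
    externalizing: CrossDisorderEdgeSet
    internalizing: CrossDisorderEdgeSet

    def assert_exclusive(self) -> None:
        g = set(self.general.members)
        e = set(self.externalizing.members)
        i = set(self.internalizing.members)
        if (g & e) or (g & i) or (e & i):
            raise AssertionError("edge taxonomy is not mutually exclusive")


@dataclass
class PermutationResult:
    """Observed count vs. its symptom-row-shuffle null."""

    observed_count: int
    null_counts: np.ndarray
    p_perm: float
    n_perm: int
    seed: int


def _domain_columns(symptom_order) -> tuple[np.ndarray, np.ndarray]:
    order = list(symptom_order)
    ext = np.array([order.index(s) for s in EXTERNALIZING_SYMPTOMS if s in order])
    ints = np.array([order.index(s) for s in INTERNALIZING_SYMPTOMS if s in order])
    return ext, ints


def _classify_matrix(
    selected: np.ndarray,
    sign: np.ndarray,
    ext_cols: np.ndarray,
    int_cols: np.ndarray,
    masked: np.ndarray | None,
) -> dict[str, np.ndarray]:
    """Vectorized taxonomy over an (edges x symptoms) selection matrix.

    Shared by :func:`classify_edges` and the permutation fast path so both
    always agree.  Returns boolean per-edge indicators.
    """
    ext_count = selected[:, ext_cols].sum(axis=1)
    int_count = selected[:, int_cols].sum(axis=1)
    in_mask = (
        masked if masked is not None else np.zeros(selected.shape[0], dtype=bool)
    )
    general = in_mask | ((ext_count >= 1) & (int_count >= 1))
    strat_ext = ~general & (ext_count >= 2) & (int_count == 0)
    strat_int = ~general & (int_count >= 2) & (ext_count == 0)

    def _uniform(strat: np.ndarray, cols: np.ndarray, want: int) -> np.ndarray:
        sub_sel = selected[:, cols]
        sub_sign = sign[:, cols]
        bad = (sub_sel & (sub_sign != want)).any(axis=1)
        return strat & ~bad

    return {
        "general": general,
        "strat_ext": strat_ext,
        "strat_int": strat_int,
        "pos_pos": _uniform(strat_ext, ext_cols, +1),
        "neg_neg": _uniform(strat_int, int_cols, -1),
    }


def _normalize_mask(general_mask, conditions, n_edges) -> dict[str, np.ndarray]:
    out = {c: np.zeros(n_edges, dtype=bool) for c in conditions}
    if general_mask is None:
        return out
    if isinstance(general_mask, dict):
        items = [(c, e) for c, idx in general_mask.items() for e in np.atleast_1d(idx)]
    else:
        items = list(general_mask)
    for cond, e in items:
        if cond in out:
            out[cond][int(e)] = True
    return out


def classify_edges(
    maps: list[EdgePredictionMap],
    general_mask=None,
) -> dict[str, ConditionTaxonomy]:
    """Build the per-condition cross-disorder taxonomy from association maps.

    ``maps`` must cover all eight symptoms for every condition it mentions.
    ``general_mask`` optionally supplies prior general-factor edges as a
    ``{condition: edge indices}`` dict or an iterable of (condition, edge)
    pairs; when absent, general edges are recomputed from the
    one-per-domain rule alone.
    """
    by_cond: dict[str, dict[str, EdgePredictionMap]] = {}
    for m in maps:
        by_cond.setdefault(m.condition, {})[m.symptom] = m
    n_edges_seen = {m.n_edges for m in maps}
    if len(n_edges_seen) != 1:
        raise ValueError(f"inconsistent edge counts across maps: {sorted(n_edges_seen)}")
    n_edges = n_edges_seen.pop()

    out: dict[str, ConditionTaxonomy] = {}
    masks = _normalize_mask(general_mask, list(by_cond), n_edges)
    for cond, sym_maps in by_cond.items():
        missing = [s for s in SYMPTOMS if s not in sym_maps]
        if missing:
            raise ValueError(f"condition {cond!r} lacks maps for symptoms {missing}")
        order = list(SYMPTOMS)
        selected = np.column_stack([sym_maps[s].selected for s in order])
        sign = np.column_stack([sym_maps[s].sign for s in order])
        ext_cols, int_cols = _domain_columns(order)
        cls = _classify_matrix(selected, sign, ext_cols, int_cols, masks[cond])

        def _build(category: str, flag: np.ndarray) -> CrossDisorderEdgeSet:
            members = [(cond, int(e)) for e in np.flatnonzero(flag)]
            support = {}
            for cond_, e in members:
                hit = np.flatnonzero(selected[e])
                support[(cond_, e)] = tuple(
                    (order[k], int(sign[e, k])) for k in hit
                )
            return CrossDisorderEdgeSet(category=category, members=members, support=support)

        tax = ConditionTaxonomy(
            condition=cond,
            general=_build(CATEGORY_GENERAL, cls["general"]),
            externalizing=_build(CATEGORY_EXT, cls["strat_ext"]),
            internalizing=_build(CATEGORY_INT, cls["strat_int"]),
        )
        tax.assert_exclusive()
        out[cond] = tax
    return out


def split_sign_groups(
    edge_set: CrossDisorderEdgeSet,
) -> dict[str, CrossDisorderEdgeSet]:
    """Partition a stratified set by uniform support sign.

    Returns pos-pos / neg-neg / mixed subsets; the partition is exhaustive
    and disjoint.  Mixed-sign edges are excluded from factor construction.
    """
    groups: dict[str, list[Member]] = {SIGN_POS: [], SIGN_NEG: [], SIGN_MIXED: []}
    for member in edge_set.members:
        groups[edge_set.member_sign_group(member)].append(member)
    return {
        name: CrossDisorderEdgeSet(
            category=edge_set.category,
            members=members,
            support={m: edge_set.support.get(m, ()) for m in members},
            sign_group=name,
        )
        for name, members in groups.items()
    }


def factor_score(connectomes, edge_set: CrossDisorderEdgeSet) -> pd.DataFrame:
    """Per-subject summed FC strength over the edge set's members.

    ``connectomes`` maps either ``condition -> (subjects x edges)`` (single
    wave; output column ``score``) or ``(condition, wave) -> matrix`` (one
    output column per wave, re-applying the same fixed edge set at every
    wave).  An empty edge set scores 0 for every subject.
    """
    keys = list(connectomes)
    waved = bool(keys) and isinstance(keys[0], tuple)
    by_cond: dict[str, list[int]] = {}
    for cond, e in edge_set.members:
        by_cond.setdefault(cond, []).append(e)

    conds_avail = {k[0] for k in keys} if waved else set(keys)
    missing = sorted(set(by_cond) - conds_avail)
    if missing:
        raise ValueError(f"edge set references absent conditions: {missing}")

    if waved:
        waves = sorted({k[1] for k in keys}, key=[k[1] for k in keys].index)
    else:
        waves = ["score"]
    n = next(iter(connectomes.values())).shape[0]
    out = np.zeros((n, len(waves)))
    for w, wave in enumerate(waves):
        for cond, edges in by_cond.items():
            mat = connectomes[(cond, wave)] if waved else connectomes[cond]
            out[:, w] += np.asarray(mat, dtype=float)[:, edges].sum(axis=1)
    return pd.DataFrame(out, columns=waves)


def count_permutation_test(
    connectomes: dict[str, np.ndarray],
    symptoms: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    general_mask=None,
) -> dict[tuple[str, str], PermutationResult]:
    """Permutation reliability of stratified-edge counts, per condition.

    For each permutation the subject rows of the symptom table are shuffled
    jointly across all symptoms and the full edge-wise association +
    classification chain is re-run.  Returns add-one permutation p-values
    for the stratified counts per condition, keyed by category:
    ``stratified-externalizing`` / ``stratified-internalizing`` (all sign
    groups), their factor-defining sign groups ``pos-pos`` / ``neg-neg``,
    and ``stratified-total``.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19")
    sym = symptoms[list(SYMPTOMS)].to_numpy(dtype=float)
    n = sym.shape[0]
    design, n_cov = design_matrix(covariates, n)
    if n <= n_cov + 3:
        raise ValueError("too few subjects for the covariate set")
    basis = orthonormal_basis(design)
    df = n - 2 - n_cov
    ext_cols, int_cols = _domain_columns(SYMPTOMS)
    masks = _normalize_mask(
        general_mask, list(connectomes), next(iter(connectomes.values())).shape[1]
    )

    # pre-residualize FC once per condition: covariates are never shuffled
    prepared = {}
    for cond, x in connectomes.items():
        xr = residualize(np.asarray(x, dtype=float), basis)
        xn = np.linalg.norm(xr, axis=0)
        zero_var = xn <= 1e-12 * np.sqrt(n)
        xn = np.where(zero_var, 1.0, xn)
        prepared[cond] = (xr / xn, zero_var)

    categories = (
        CATEGORY_EXT,
        CATEGORY_INT,
        SIGN_POS,
        SIGN_NEG,
        "stratified-total",
    )

    def _counts(perm: np.ndarray | None) -> dict[tuple[str, str], int]:
        s = sym if perm is None else sym[perm]
        sr = residualize(s, basis)
        sn = np.linalg.norm(sr, axis=0)
        if np.any(sn <= 1e-12 * np.sqrt(n)):
            raise ValueError("symptom with zero residual variance")
        sr = sr / sn
        out: dict[tuple[str, str], int] = {}
        for cond, (xhat, zero_var) in prepared.items():
            r = np.clip(xhat.T @ sr, -1.0, 1.0)
            p = _p_from_r(r, df)
            p[zero_var] = 1.0
            selected = p <= alpha
            sign = np.sign(r).astype(np.int8)
            cls = _classify_matrix(selected, sign, ext_cols, int_cols, masks[cond])
            out[(cond, CATEGORY_EXT)] = int(cls["strat_ext"].sum())
            out[(cond, CATEGORY_INT)] = int(cls["strat_int"].sum())
            out[(cond, SIGN_POS)] = int(cls["pos_pos"].sum())
            out[(cond, SIGN_NEG)] = int(cls["neg_neg"].sum())
            out[(cond, "stratified-total")] = (
                out[(cond, CATEGORY_EXT)] + out[(cond, CATEGORY_INT)]
            )
        return out

    observed = _counts(None)
    rng = np.random.default_rng(seed)
    nulls = {key: np.empty(n_perm, dtype=int) for key in observed}
    for b in range(n_perm):
        perm = rng.permutation(n)
        for key, c in _counts(perm).items():
            nulls[key][b] = c

    results = {}
    for key, obs in observed.items():
        null = nulls[key]
        p = (int((null >= obs).sum()) + 1) / (n_perm + 1)
        results[key] = PermutationResult(
            observed_count=obs, null_counts=null, p_perm=p, n_perm=n_perm, seed=seed
        )
    return results
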