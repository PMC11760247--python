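"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results with plain per-item loops, independent
of the vectorized implementation paths they check.
"""

import numpy as np

from stratnet.brain_behavior import EdgePredictionMap
from stratnet.simulate import DOMAIN_OF, SYMPTOMS


def make_map(condition, symptom, selected, sign, alpha=0.05, rng=None):
    """Assemble an EdgePredictionMap from a selection/sign pattern."""
    selected = np.asarray(selected, dtype=bool)
    sign = np.asarray(sign, dtype=np.int8)
    n_edges = selected.size
    rng = rng or np.random.default_rng(0)
    p = np.where(selected, alpha * rng.random(n_edges), alpha + (1 - alpha) * rng.random(n_edges))
    r = np.where(selected, sign * (0.1 + 0.4 * rng.random(n_edges)), 0.01 * rng.standard_normal(n_edges))
    return EdgePredictionMap(
        condition=condition,
        symptom=symptom,
        alpha=alpha,
        r=r,
        p=p,
        selected=selected,
        sign=np.where(selected, sign, 0).astype(np.int8),
        zero_variance=np.zeros(n_edges, dtype=bool),
        n=100,
        n_covariates=0,
    )


def taxonomy_oracle(maps_one_condition, general_mask_edges=()):
    """Enumerate every edge's support pattern independently.

    Returns dict edge -> (category, sign_group, support) with category in
    {None, "general", "ext", "int"}.
    """
    by_symptom = {m.symptom: m for m in maps_one_condition}
    n_edges = next(iter(by_symptom.values())).n_edges
    masked = set(general_mask_edges)
    out = {}
    for e in range(n_edges):
        support = []
        for s in SYMPTOMS:
            m = by_symptom[s]
            if m.selected[e]:
                support.append((s, int(m.sign[e])))
        n_ext = sum(1 for s, _ in support if DOMAIN_OF[s] == "externalizing")
        n_int = sum(1 for s, _ in support if DOMAIN_OF[s] == "internalizing")
        if e in masked or (n_ext >= 1 and n_int >= 1):
            cat = "general"
        elif n_ext >= 2 and n_int == 0:
            cat = "ext"
        elif n_int >= 2 and n_ext == 0:
            cat = "int"
        else:
            cat = None
        signs = {g for _, g in support}
        if signs == {1}:
            sg = "pos-pos"
        elif signs == {-1}:
            sg = "neg-neg"
        else:
            sg = "mixed"
        out[e] = (cat, sg, tuple(support))
    return out


def specificity_oracle(raw_np, raw_ext, raw_int):
    """Recompute every ratio from raw degrees with plain loops."""
    raws = [np.asarray(v, dtype=float) for v in (raw_np, raw_ext, raw_int)]
    norms = [v / v.sum() + 1.0 for v in raws]
    n = len(norms[0])
    scores = np.empty((n, 3))
    for u in range(n):
        for f in range(3):
            others = [k for k in range(3) if k != f]
            scores[u, f] = (
                norms[f][u] / norms[others[0]][u] + norms[f][u] / norms[others[1]][u]
            )
    return norms, scores
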