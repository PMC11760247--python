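import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stratnet import specificity as sp
from stratnet.factors import CATEGORY_EXT, CrossDisorderEdgeSet
from stratnet.parcellation import generate_parcellation

from _oracles import specificity_oracle


def _edge_set(parc, pairs, conditions=("c",)):
    members = [(c, int(parc.pair_to_index(i, j))) for c in conditions for i, j in pairs]
    return CrossDisorderEdgeSet(CATEGORY_EXT, members)


def test_node_degree_single_edge_and_triangle():
    parc = generate_parcellation(6, 2, seed=0)
    deg = sp.node_degree(_edge_set(parc, [(0, 1)]), parc)
    assert deg.tolist() == [1, 1, 0, 0, 0, 0]
    deg = sp.node_degree(_edge_set(parc, [(0, 1), (1, 2), (0, 2)]), parc)
    assert deg.tolist() == [2, 2, 2, 0, 0, 0]


def test_node_degree_counts_conditions_separately():
    parc = generate_parcellation(5, 2, seed=0)
    es = _edge_set(parc, [(0, 1)], conditions=("c1", "c2"))
    assert sp.node_degree(es, parc).tolist() == [2, 2, 0, 0, 0]


def test_normalize_degree_examples():
    np.testing.assert_allclose(
        sp.normalize_degree(np.array([2, 2, 0])), [1.5, 1.5, 1.0]
    )
    k = 7
    np.testing.assert_allclose(sp.normalize_degree(np.full(k, 3)), 1 + 1 / k)
    with pytest.raises(ValueError, match="empty factor"):
        sp.normalize_degree(np.zeros(4))


@settings(derandomize=True, max_examples=60)
@given(
    raw=st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=30).filter(
        lambda v: sum(v) > 0
    )
)
def test_normalized_degree_always_in_unit_band(raw):
    out = sp.normalize_degree(np.array(raw, dtype=float))
    assert np.all(out >= 1.0) and np.all(out <= 2.0)
    assert np.isclose((out - 1).sum(), 1.0)


def test_specificity_equal_profile_scores_exactly_two():
    v = np.full(5, 1.3)
    table = sp.specificity_scores(v, v, v)
    for f in sp.FACTOR_ORDER:
        assert (table[f"spec_{f}"] == 2.0).all()
    assert (table["spec_distance"] == 0.0).all()
    # tie broken by fixed factor order
    assert (table["predominant_factor"] == "NP").all()


def test_specificity_hand_computed_example():
    table = sp.specificity_scores(
        np.array([1.5]), np.array([1.2]), np.array([1.1])
    )
    assert table["spec_NP"][0] == pytest.approx(1.5 / 1.2 + 1.5 / 1.1, abs=1e-12)
    assert table["predominant_factor"][0] == "NP"
    scores = table[[f"spec_{f}" for f in sp.FACTOR_ORDER]].to_numpy()[0]
    assert table["spec_distance"][0] == pytest.approx(scores.max() - scores.min())


def test_specificity_matches_bruteforce_oracle(rng):
    for _ in range(20):
        n = int(rng.integers(3, 40))
        raws = [rng.integers(1, 30, n).astype(float) for _ in range(3)]
        norms, want = specificity_oracle(*raws)
        table = sp.specificity_scores(*norms)
        got = table[[f"spec_{f}" for f in sp.FACTOR_ORDER]].to_numpy()
        np.testing.assert_allclose(got, want, atol=1e-12)


def test_label_swap_permutes_scores_identically(rng):
    n = 10
    a, b, c = (1 + rng.random(n) for _ in range(3))
    t1 = sp.specificity_scores(a, b, c)
    t2 = sp.specificity_scores(b, a, c)
    np.testing.assert_allclose(t1["spec_NP"], t2["spec_externalizing"], atol=1e-14)
    np.testing.assert_allclose(t1["spec_externalizing"], t2["spec_NP"], atol=1e-14)


def test_unit_permutation_equivariance(rng):
    n = 12
    a, b, c = (1 + rng.random(n) for _ in range(3))
    perm = rng.permutation(n)
    t = sp.specificity_scores(a, b, c)
    tp = sp.specificity_scores(a[perm], b[perm], c[perm])
    np.testing.assert_allclose(
        t["spec_NP"].to_numpy()[perm], tp["spec_NP"].to_numpy(), atol=1e-14
    )
    assert list(t["predominant_factor"].to_numpy()[perm]) == list(
        tp["predominant_factor"]
    )


def test_out_of_band_normalized_degrees_rejected():
    v = np.array([1.0, 2.1])
    with pytest.raises(ValueError):
        sp.specificity_scores(v, np.ones(2), np.ones(2))


# --- network aggregation --------------------------------------------------


def test_network_aggregate_single_network_block():
    parc = generate_parcellation(6, 3, seed=0)  # blocks {0,1},{2,3},{4,5}
    mat = sp.network_aggregate(_edge_set(parc, [(0, 1)]), parc)
    assert mat[0, 0] == 1.0
    assert mat.sum() == 1.0


def test_network_aggregate_ratio_and_symmetry():
    parc = generate_parcellation(6, 3, seed=0)
    pairs = [(0, 2), (1, 2), (0, 3), (1, 3), (0, 4), (2, 4)]
    # network pair (0,1): 4 edges; (0,2): 1; (1,2): 1
    mat = sp.network_aggregate(_edge_set(parc, pairs), parc)
    assert mat[0, 1] == 1.0 and mat[1, 0] == 1.0
    assert mat[0, 2] == 0.25
    assert np.allclose(mat, mat.T)
    assert mat.max() == 1.0


def test_network_aggregate_empty_set_warns():
    parc = generate_parcellation(6, 3, seed=0)
    es = CrossDisorderEdgeSet(CATEGORY_EXT, [])
    mat = sp.network_aggregate(es, parc)
    assert (mat == 0).all()


def test_network_pair_counts_has_m_choose_2_plus_m_units():
    parc = generate_parcellation(8, 4, seed=0)
    es = _edge_set(parc, [(0, 7)])
    counts = sp.network_pair_counts(es, parc)
    assert counts.shape == (4 * 5 // 2,)
    assert counts.sum() == 1
    assert len(sp.network_pair_labels(parc)) == 10


# --- level comparison -----------------------------------------------------


def test_identical_profiles_give_zero_anova_f(rng):
    v = 1 + rng.random(20)
    table = sp.specificity_scores(v, v, v)
    cmp_ = sp.compare_specificity_levels(table, table)["region"]
    assert cmp_.anova_f == pytest.approx(0.0, abs=1e-12)


def test_predominance_counts_partition_units(rng):
    a, b, c = (1 + rng.random(30) for _ in range(3))
    table = sp.specificity_scores(a, b, c)
    cmp_ = sp.compare_specificity_levels(table, table)["region"]
    assert sum(cmp_.predominance_counts.values()) == 30


def test_scaled_up_factor_wins_predominance(rng):
    raw = rng.integers(1, 10, 25).astype(float)
    boosted = raw.copy()
    boosted[:15] *= 6  # externalizing dominates most units
    norms = [sp.normalize_degree(v) for v in (raw, boosted, raw)]
    table = sp.specificity_scores(*norms)
    cmp_ = sp.compare_specificity_levels(table, table)["region"]
    counts = cmp_.predominance_counts
    assert counts["externalizing"] == max(counts.values())


def test_region_specificity_distance_exceeds_network_level():
    """Coarse-fine gradient: factors with distinct hub regions but shared
    network configurations are more separable at the region level."""
    parc = generate_parcellation(30, 5, seed=0)  # contiguous blocks of 6
    blocks = [np.flatnonzero(parc.network_of == k) for k in range(5)]
    # each factor's edges connect its own hub nodes across every network pair,
    # so the three factors occupy disjoint regions yet identical network pairs
    sets = {}
    for f, name in enumerate(("NP", "externalizing", "internalizing")):
        pairs = []
        for a in range(5):
            for b in range(a, 5):
                i = blocks[a][2 * f]
                j = blocks[b][2 * f + 1]
                pairs.append((min(i, j), max(i, j)))
        sets[name] = _edge_set(parc, pairs)
    region_norms = {
        k: sp.normalize_degree(sp.node_degree(v, parc)) for k, v in sets.items()
    }
    net_norms = {
        k: sp.normalize_degree(sp.network_pair_counts(v, parc))
        for k, v in sets.items()
    }
    region = sp.specificity_scores(
        region_norms["NP"], region_norms["externalizing"], region_norms["internalizing"]
    )
    network = sp.specificity_scores(
        net_norms["NP"], net_norms["externalizing"], net_norms["internalizing"]
    )
    assert region["spec_distance"].mean() >= network["spec_distance"].mean()
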