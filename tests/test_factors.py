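import numpy as np
import pytest

from stratnet import SYMPTOMS, brain_behavior as bb, factors
from stratnet.factors import (
    CATEGORY_EXT,
    CATEGORY_INT,
    SIGN_MIXED,
    SIGN_NEG,
    SIGN_POS,
    CrossDisorderEdgeSet,
)

from _oracles import make_map, taxonomy_oracle
from conftest import wave1_views


def _maps_from_pattern(pattern, n_edges=4, condition="c"):
    """pattern: {symptom: {edge: sign}}; all other entries unselected."""
    maps = []
    for s in SYMPTOMS:
        sel = np.zeros(n_edges, dtype=bool)
        sign = np.zeros(n_edges, dtype=int)
        for e, g in pattern.get(s, {}).items():
            sel[e] = True
            sign[e] = g
        maps.append(make_map(condition, s, sel, sign))
    return maps


def test_two_same_domain_positive_supports_is_stratified_pos_pos():
    maps = _maps_from_pattern({"ADHD": {0: 1}, "CD": {0: 1}})
    tax = factors.classify_edges(maps)["c"]
    assert tax.externalizing.members == [("c", 0)]
    assert tax.externalizing.member_sign_group(("c", 0)) == SIGN_POS
    assert tax.general.members == [] and tax.internalizing.members == []


def test_cross_domain_support_is_general():
    maps = _maps_from_pattern({"ADHD": {1: 1}, "Depression": {1: -1}})
    tax = factors.classify_edges(maps)["c"]
    assert tax.general.members == [("c", 1)]
    assert tax.externalizing.members == []


def test_single_support_is_not_cross_disorder():
    maps = _maps_from_pattern({"ADHD": {2: 1}})
    tax = factors.classify_edges(maps)["c"]
    assert tax.general.members == []
    assert tax.externalizing.members == []
    assert tax.internalizing.members == []


def test_mixed_sign_stratified_edge_lands_in_mixed_group():
    maps = _maps_from_pattern({"GAD": {3: -1}, "ED": {3: 1}})
    tax = factors.classify_edges(maps)["c"]
    assert tax.internalizing.members == [("c", 3)]
    groups = factors.split_sign_groups(tax.internalizing)
    assert groups[SIGN_MIXED].members == [("c", 3)]
    assert groups[SIGN_NEG].members == []


def test_general_mask_removes_edge_from_stratified():
    maps = _maps_from_pattern({"ADHD": {0: 1}, "CD": {0: 1}})
    tax = factors.classify_edges(maps, general_mask={"c": [0]})["c"]
    assert tax.externalizing.members == []
    assert tax.general.members == [("c", 0)]


def test_inconsistent_edge_counts_rejected():
    m1 = _maps_from_pattern({}, n_edges=4)
    m2 = _maps_from_pattern({}, n_edges=5)
    with pytest.raises(ValueError):
        factors.classify_edges(m1[:4] + m2[4:])


def test_missing_symptom_rejected():
    maps = _maps_from_pattern({})[:-1]
    with pytest.raises(ValueError):
        factors.classify_edges(maps)


def test_classification_matches_bruteforce_on_random_maps(rng):
    for _ in range(100):
        n_edges = int(rng.integers(5, 50))
        maps = []
        for s in SYMPTOMS:
            sel = rng.random(n_edges) < 0.25
            sign = rng.choice([-1, 1], n_edges)
            maps.append(make_map("c", s, sel, sign, rng=rng))
        mask = rng.choice(n_edges, size=min(3, n_edges), replace=False)
        tax = factors.classify_edges(maps, general_mask={"c": mask})["c"]
        oracle = taxonomy_oracle(maps, general_mask_edges=set(int(m) for m in mask))
        want = {
            "general": {e for e, (cat, _, _) in oracle.items() if cat == "general"},
            "ext": {e for e, (cat, _, _) in oracle.items() if cat == "ext"},
            "int": {e for e, (cat, _, _) in oracle.items() if cat == "int"},
        }
        assert {e for _, e in tax.general.members} == want["general"]
        assert {e for _, e in tax.externalizing.members} == want["ext"]
        assert {e for _, e in tax.internalizing.members} == want["int"]


def test_taxonomy_is_mutually_exclusive_on_planted_cohort(planted_small_study):
    conn, sym, cov = wave1_views(planted_small_study)
    maps = [
        bb.edgewise_association(conn[c], sym[s].to_numpy(), cov, 0.05,
                                condition=c, symptom_name=s)
        for c in conn
        for s in SYMPTOMS
    ]
    for tax in factors.classify_edges(maps).values():
        tax.assert_exclusive()  # raises on violation
        groups = factors.split_sign_groups(tax.externalizing)
        members = [m for g in groups.values() for m in g.members]
        assert sorted(members) == sorted(tax.externalizing.members)


def test_sign_group_partition_is_exhaustive_and_disjoint():
    es = CrossDisorderEdgeSet(
        CATEGORY_EXT,
        [("c", 0), ("c", 1), ("c", 2)],
        support={
            ("c", 0): (("ADHD", 1), ("CD", 1)),
            ("c", 1): (("ADHD", -1), ("CD", -1)),
            ("c", 2): (("ADHD", 1), ("CD", -1)),
        },
    )
    groups = factors.split_sign_groups(es)
    assert groups[SIGN_POS].members == [("c", 0)]
    assert groups[SIGN_NEG].members == [("c", 1)]
    assert groups[SIGN_MIXED].members == [("c", 2)]


# --- factor scores --------------------------------------------------------


def test_factor_score_arithmetic():
    conn = {"c": np.array([[0.2, -0.1, 0.4], [0.7, 0.0, 0.0]])}
    es = CrossDisorderEdgeSet(CATEGORY_EXT, [("c", 0), ("c", 1), ("c", 2)])
    scores = factors.factor_score(conn, es)["score"]
    assert scores.tolist() == pytest.approx([0.5, 0.7])
    one = CrossDisorderEdgeSet(CATEGORY_EXT, [("c", 0)])
    assert factors.factor_score(conn, one)["score"].tolist() == pytest.approx([0.2, 0.7])


def test_empty_edge_set_scores_zero():
    conn = {"c": np.random.default_rng(0).normal(size=(5, 4))}
    es = CrossDisorderEdgeSet(CATEGORY_EXT, [])
    assert (factors.factor_score(conn, es)["score"] == 0).all()


def test_factor_score_missing_condition_error():
    conn = {"c": np.zeros((3, 4))}
    es = CrossDisorderEdgeSet(CATEGORY_EXT, [("other", 0)])
    with pytest.raises(ValueError, match="other"):
        factors.factor_score(conn, es)


def test_factor_score_reapplies_same_edges_per_wave():
    conn = {
        ("c", "w1"): np.array([[1.0, 2.0]]),
        ("c", "w2"): np.array([[3.0, 5.0]]),
    }
    es = CrossDisorderEdgeSet(CATEGORY_EXT, [("c", 1)])
    out = factors.factor_score(conn, es)
    assert out["w1"].tolist() == [2.0] and out["w2"].tolist() == [5.0]


# --- permutation count test ----------------------------------------------


def test_permutation_observed_matches_classify_chain(noise_study):
    conn, sym, cov = wave1_views(noise_study)
    maps = [
        bb.edgewise_association(conn["c1"], sym[s].to_numpy(), cov, 0.05,
                                condition="c1", symptom_name=s)
        for s in SYMPTOMS
    ]
    tax = factors.classify_edges(maps)["c1"]
    res = factors.count_permutation_test(conn, sym, cov, n_perm=99, seed=4)
    assert res[("c1", CATEGORY_EXT)].observed_count == tax.externalizing.n_edges
    assert res[("c1", CATEGORY_INT)].observed_count == tax.internalizing.n_edges
    total = res[("c1", "stratified-total")]
    assert total.observed_count == tax.externalizing.n_edges + tax.internalizing.n_edges


def test_permutation_p_follows_add_one_formula(noise_study):
    conn, sym, cov = wave1_views(noise_study)
    res = factors.count_permutation_test(conn, sym, cov, n_perm=99, seed=4)
    for r in res.values():
        expect = (int((r.null_counts >= r.observed_count).sum()) + 1) / (r.n_perm + 1)
        assert r.p_perm == pytest.approx(expect)
        assert 0 < r.p_perm <= 1


def test_permutation_is_deterministic(noise_study):
    conn, sym, cov = wave1_views(noise_study)
    a = factors.count_permutation_test(conn, sym, cov, n_perm=49, seed=9)
    b = factors.count_permutation_test(conn, sym, cov, n_perm=49, seed=9)
    for key in a:
        assert np.array_equal(a[key].null_counts, b[key].null_counts)


def test_planted_cohort_rejects_reliably(planted_small_study):
    """Planted stratified edges yield p_perm at the add-one floor."""
    conn, sym, cov = wave1_views(planted_small_study)
    res = factors.count_permutation_test(conn, sym, cov, n_perm=99, seed=2)
    for c in planted_small_study.config.conditions:
        assert res[(c, SIGN_POS)].p_perm <= 0.01
        assert res[(c, SIGN_NEG)].p_perm <= 0.01


def test_zero_observed_count_gives_p_one(noise_study):
    conn, sym, cov = wave1_views(noise_study)
    # alpha so small nothing is ever selected -> all counts 0 -> p = 1
    res = factors.count_permutation_test(conn, sym, cov, alpha=1e-12, n_perm=19, seed=0)
    for r in res.values():
        assert r.observed_count == 0
        assert r.p_perm == 1.0


def test_recovery_and_fdp_on_moderate_null_multiplicity():
    """Planted-edge recovery with bounded false-discovery proportion.

    At a 30-node parcellation (435 edges, 40+40 planted per condition) the
    factor-defining sign groups recover >= 80% of planted edges with FDP
    <= 20%, averaged over 3 seeds.  FDP grows with the number of null edges
    at fixed alpha, so the bound is specific to this null multiplicity.
    """
    from stratnet import SimulationConfig, generate_cohort

    sens_e, sens_i, fdps = [], [], []
    for seed in (0, 1, 2):
        cfg = SimulationConfig(seed=seed, n_nodes=30, n_networks=5,
                               conditions=("c1", "c2"))
        study = generate_cohort(cfg)
        conn, sym, cov = wave1_views(study)
        maps = [
            bb.edgewise_association(conn[c], sym[s].to_numpy(), cov, 0.05,
                                    condition=c, symptom_name=s)
            for c in conn
            for s in SYMPTOMS
        ]
        tax = factors.classify_edges(maps)
        got_e, got_i = set(), set()
        for c, t in tax.items():
            got_e |= set(factors.split_sign_groups(t.externalizing)[SIGN_POS].members)
            got_i |= set(factors.split_sign_groups(t.internalizing)[SIGN_NEG].members)
        tr = study.truth
        pe = {(c, int(e)) for c, v in tr.ext_edges.items() for e in v}
        pi = {(c, int(e)) for c, v in tr.int_edges.items() for e in v}
        sens_e.append(len(got_e & pe) / len(pe))
        sens_i.append(len(got_i & pi) / len(pi))
        fdps.append(
            (len(got_e - pe) + len(got_i - pi)) / max(len(got_e) + len(got_i), 1)
        )
    assert np.mean(sens_e) >= 0.8
    assert np.mean(sens_i) >= 0.8
    assert np.mean(fdps) <= 0.2
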