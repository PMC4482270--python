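import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegbm.channels import N_PAIRS, PAIR_INDEX, PAIR_UNIVERSE, pair_indices
from eegbm import networks as net
from eegbm.networks import (
    ASD_LOW_MASK,
    CONTROL_HIGH_MASK,
    INTERSECTION_MASK,
    UNION_MASK,
    EdgeMask,
    EpochNetwork,
    bh_fdr,
    combine_masks,
    degree_profile,
    density,
    mask_density,
    region,
    regional_density,
    template_network,
)


def _network(edges=(), excluded=()):
    adjacency = np.zeros(N_PAIRS, bool)
    zl = np.zeros(N_PAIRS, bool)
    if len(edges):
        adjacency[np.asarray(edges, int)] = True
    if len(excluded):
        zl[np.asarray(excluded, int)] = True
    return EpochNetwork(adjacency=adjacency, zero_lag_excluded=zl)


def _brute_force_stepup(p, q):
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order]
    passing = [k for k in range(m) if ranked[k] <= q * (k + 1) / m]
    out = np.zeros(m, bool)
    if passing:
        out[order[: passing[-1] + 1]] = True
    return out


def test_bh_fdr_hand_examples():
    assert bh_fdr(np.ones(5)).sum() == 0
    rej = bh_fdr([0.001, 0.02, 0.9], q=0.05)
    np.testing.assert_array_equal(rej, [True, True, False])
    assert bh_fdr([]).size == 0


def test_bh_fdr_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.integers(0, 2**31 - 1), st.floats(0.01, 0.3))
def test_bh_fdr_matches_brute_force_stepup(seed, q):
    p = np.random.default_rng(seed).uniform(size=40)
    np.testing.assert_array_equal(bh_fdr(p, q), _brute_force_stepup(p, q))


def test_network_invariants():
    with pytest.raises(ValueError):
        EpochNetwork(adjacency=np.ones(N_PAIRS, bool),
                     zero_lag_excluded=np.ones(N_PAIRS, bool))
    with pytest.raises(ValueError):
        EpochNetwork(adjacency=np.zeros(10, bool),
                     zero_lag_excluded=np.zeros(10, bool))


def test_density_printed_denominator_rule():
    assert density(_network()) == 0.0
    nw = _network(edges=range(10), excluded=range(150, 153))
    assert density(nw) == pytest.approx(10 / 150)


def test_density_undefined_when_all_excluded():
    with pytest.raises(ValueError, match="undefined"):
        density(_network(excluded=range(N_PAIRS)))


def test_degree_star_and_handshake(rng):
    # star on Fp1-F7: edges to its first k partners
    k = 5
    star_edges = [PAIR_INDEX[frozenset(("Fp1-F7", other))]
                  for other in ("F7-T3", "T3-T5", "T5-O1", "Fp1-F3", "F3-C3")]
    deg = degree_profile(_network(edges=star_edges))
    assert deg[0] == k
    assert sorted(deg)[-1] == k
    assert deg.sum() == 2 * k
    # handshake lemma on a random network
    nw = _network(edges=rng.choice(N_PAIRS, size=30, replace=False))
    assert degree_profile(nw).sum() == 2 * nw.n_edges


def test_regional_density_consistency(rng):
    nw = _network(edges=rng.choice(N_PAIRS, size=25, replace=False))
    assert regional_density(nw, "all") == pytest.approx(density(nw))


def test_left_only_edges_give_zero_right_density():
    left = [i for i, (a, b) in enumerate(PAIR_UNIVERSE)
            if {a, b} <= {"Fp1-F7", "F7-T3", "T3-T5", "T5-O1"}]
    nw = _network(edges=left[:4])
    assert regional_density(nw, "right") == 0.0
    assert regional_density(nw, "left") > 0.0


def test_regional_density_toy_hand_count():
    spec = region("interhemispheric_LR")
    mask = spec.pair_mask()
    chosen = np.flatnonzero(mask)[:6]
    nw = _network(edges=chosen)
    assert regional_density(nw, spec) == pytest.approx(6 / mask.sum())


def test_unknown_region_rejected():
    with pytest.raises(ValueError, match="unknown region"):
        region("occipital")


def test_template_network_proportions():
    always = _network(edges=[0])
    never = _network()
    tpl = template_network([always, never, never, never])
    assert tpl.weights[0] == pytest.approx(0.25)
    tpl_all = template_network([always] * 4)
    assert tpl_all.weights[0] == 1.0
    assert tpl_all.weights[1] == 0.0


def test_group_template_bounded_by_subject_weights(rng):
    subject_templates = [
        template_network([_network(edges=rng.choice(N_PAIRS, rng.integers(5, 30),
                                                    replace=False))
                          for _ in range(6)])
        for _ in range(5)
    ]
    group = template_network(subject_templates, "group")
    stack = np.stack([t.weights for t in subject_templates])
    assert np.all(group.weights >= stack.min(axis=0) - 1e-12)
    assert np.all(group.weights <= stack.max(axis=0) + 1e-12)


def test_mask_density_definitions():
    full = EdgeMask("full", PAIR_UNIVERSE)
    nw = _network(edges=range(12))
    assert mask_density(nw, full) == pytest.approx(density(nw))
    two_of_seven = _network(edges=INTERSECTION_MASK.indices()[:2])
    assert mask_density(two_of_seven, INTERSECTION_MASK) == pytest.approx(2 / 7)


def test_mask_density_excluded_edges_count_absent():
    nw = _network(excluded=INTERSECTION_MASK.indices())
    assert mask_density(nw, INTERSECTION_MASK) == 0.0


def test_empty_mask_rejected():
    with pytest.raises(ValueError, match="mask"):
        mask_density(_network(), EdgeMask("empty", ()))


def test_published_mask_counts():
    assert len(ASD_LOW_MASK) == 16
    assert len(CONTROL_HIGH_MASK) == 23
    assert len(INTERSECTION_MASK) == 7
    assert len(UNION_MASK) == 32


def test_intersection_mask_edges():
    expected = {
        frozenset(("Fp1-F3", "Fp1-F7")), frozenset(("F3-C3", "F7-T3")),
        frozenset(("C3-P3", "T3-T5")), frozenset(("P3-O1", "T5-O1")),
        frozenset(("C4-P4", "T4-T6")), frozenset(("C4-P4", "Cz-Pz")),
        frozenset(("P4-O2", "T6-O2")),
    }
    assert {frozenset(p) for p in INTERSECTION_MASK.pairs} == expected


def test_combine_masks_modes():
    assert combine_masks(ASD_LOW_MASK, CONTROL_HIGH_MASK, "asd_only").pairs == \
        tuple(PAIR_UNIVERSE[i] for i in ASD_LOW_MASK.indices())
    with pytest.raises(ValueError, match="mode"):
        combine_masks(ASD_LOW_MASK, CONTROL_HIGH_MASK, "xor")


def test_mask_file_round_trip(tmp_path):
    path = tmp_path / "mask.txt"
    UNION_MASK.to_file(path)
    text = path.read_text()
    assert "Fp1-F7/Fp1-F3" in text  # canonical chain order within the pair
    back = EdgeMask.from_file(path, name="union")
    assert {frozenset(p) for p in back.pairs} == \
        {frozenset(p) for p in UNION_MASK.pairs}


def test_mask_rejects_unknown_pair():
    with pytest.raises(ValueError):
        EdgeMask("bad", (("Fp1-F7", "Xx-Yy"),))


def test_monotone_under_edge_addition(rng):
    base_edges = list(rng.choice(N_PAIRS, size=10, replace=False))
    extra = [i for i in range(N_PAIRS) if i not in base_edges][:5]
    small = _network(edges=base_edges)
    large = _network(edges=base_edges + extra)
    assert density(large) >= density(small)
    assert mask_density(large, UNION_MASK) >= mask_density(small, UNION_MASK)
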