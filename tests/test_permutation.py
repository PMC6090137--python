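"""Sign-flip location test and QAP network correlation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fbinet as fb
from fbinet.networks import FUNGI_TO_BACTERIA, BipartiteNetwork

grade_lists = st.lists(
    st.integers(min_value=-6, max_value=6), min_size=1, max_size=12
)


def test_exhaustive_oracle_tied_grades():
    """[5,5,6,6]: of the 16 sign assignments of the signed-rank sum only
    all-plus and all-minus reach |T|=10, so p = 2/16 = 0.125."""
    res = fb.median_location_test([5, 5, 6, 6])
    assert res.method == "exhaustive"
    assert res.p_value == 0.125
    assert res.n_perm == 16
    assert res.estimate == 5.5


def test_exhaustive_single_value():
    """One nonzero grade: both assignments are equally extreme, p=1."""
    res = fb.median_location_test([4])
    assert res.p_value == 1.0 and res.method == "exhaustive"


def test_all_zero_grades_degenerate():
    res = fb.median_location_test([0, 0, 0])
    assert res.p_value == 1.0 and res.estimate == 0.0 and res.degenerate


def test_empty_rejected():
    with pytest.raises(ValueError):
        fb.median_location_test([])


@given(grades=grade_lists)
@settings(derandomize=True, max_examples=60)
def test_sign_symmetry(grades):
    a = fb.median_location_test(grades)
    b = fb.median_location_test([-g for g in grades])
    assert b.p_value == a.p_value
    assert b.estimate == -a.estimate


@pytest.mark.parametrize(
    "grades",
    [[5, 5, 6, 6], [1, 2, 3, -4, 5, 6], [-6, -6, -5, 3, 3], [2, 2, 2, 2, 2, 2, 2]],
)
def test_monte_carlo_agrees_with_exhaustive(grades):
    """At 10,000 draws the Monte-Carlo p lies within 3 binomial standard
    errors of the exact enumeration value."""
    exact = fb.median_location_test(grades, method="exhaustive")
    mc = fb.median_location_test(grades, method="monte_carlo", n_perm=10_000, seed=31)
    se = np.sqrt(exact.p_value * (1 - exact.p_value) / 10_000)
    assert abs(mc.p_value - exact.p_value) <= 3 * se + 2 / 10_000


def test_location_test_type_one_error_under_symmetric_null():
    """Random-sign grades (p=1/2) rejected at alpha=0.05 in at most 6%
    of 10,000 replicates (exact p-values are valid, hence conservative
    on the discrete support)."""
    rng = np.random.default_rng(99)
    rejections = 0
    n_rep = 10_000
    for _ in range(n_rep):
        m = rng.integers(5, 15)
        grades = rng.integers(1, 7, size=m) * rng.choice([-1, 1], size=m)
        if fb.median_location_test(grades).p_value < 0.05:
            rejections += 1
    assert rejections / n_rep <= 0.06


def test_dominance_summary_verdicts(stress_result, null_result):
    dom = stress_result.dominance.set_index(["medium", "direction"])
    for direction in ("fungi_to_bacteria", "bacteria_to_fungi"):
        assert dom.loc[("MM", direction), "verdict"] == "inductions dominate"
        assert dom.loc[("PDA", direction), "verdict"] == "repressions dominate"
    # verdict never contradicts the median sign
    for table in (stress_result.dominance, null_result.dominance):
        for r in table.itertuples():
            if r.verdict == "inductions dominate":
                assert r.median > 0 and r.p_value < 0.05
            elif r.verdict == "repressions dominate":
                assert r.median < 0 and r.p_value < 0.05


def test_dominance_all_zero_networks():
    sources, targets = ("F1", "F2"), ("B1", "B2")
    nets = [
        BipartiteNetwork(m, FUNGI_TO_BACTERIA, sources, targets, np.zeros((2, 2)))
        for m in ("CP", "MM")
    ]
    dom = fb.dominance_summary(nets)
    assert (dom["verdict"] == "no dominance").all()
    assert (dom["p_value"] == 1.0).all()


def test_qap_self_and_negated_correlation():
    rng = np.random.default_rng(0)
    w = rng.integers(-6, 7, size=(4, 5))
    same = fb.qap_correlation(w, w, seed=1)
    assert same.estimate == pytest.approx(1.0)
    neg = fb.qap_correlation(w, -w, seed=1)
    assert neg.estimate == pytest.approx(-1.0)
    assert 0 < same.p_value <= 1


def test_qap_constant_matrix_rejected():
    w = np.arange(20).reshape(4, 5)
    with pytest.raises(ValueError, match="constant"):
        fb.qap_correlation(w, np.zeros((4, 5)))
    with pytest.raises(ValueError, match="shape"):
        fb.qap_correlation(w, np.zeros((5, 4)))


def test_qap_invariant_under_joint_relabelling():
    """Applying one row and one column permutation to BOTH matrices
    leaves the observed correlation unchanged."""
    rng = np.random.default_rng(3)
    w1 = rng.integers(-6, 7, size=(4, 5)).astype(float)
    w2 = rng.integers(-6, 7, size=(4, 5)).astype(float)
    r0 = fb.qap_correlation(w1, w2, n_perm=10, seed=0).estimate
    rp = rng.permutation(4)
    cp = rng.permutation(5)
    r1 = fb.qap_correlation(
        w1[rp][:, cp], w2[rp][:, cp], n_perm=10, seed=0
    ).estimate
    assert r1 == pytest.approx(r0, abs=1e-12)


def test_qap_deterministic_given_seed():
    rng = np.random.default_rng(8)
    w1 = rng.integers(-6, 7, size=(4, 5))
    w2 = rng.integers(-6, 7, size=(4, 5))
    a = fb.qap_correlation(w1, w2, seed=77)
    b = fb.qap_correlation(w1, w2, seed=77)
    assert a == b


def test_qap_all_pairs_layout(stress_result):
    """4 media give 6 unordered pairs per direction; undefined pairs are
    reported with an error message while the rest complete."""
    for direction, table in stress_result.qap.items():
        assert len(table) == 6
        assert (table["direction"] == direction).all()
        defined = table[table["error"] == ""]
        assert ((defined["p_value"] > 0) & (defined["p_value"] <= 1)).all()


def test_qap_all_pairs_duplicate_networks_have_unit_r():
    rng = np.random.default_rng(12)
    w = rng.integers(-6, 7, size=(4, 5))
    sources = ("F1", "F2", "F3", "F4")
    targets = ("B1", "B2", "B3", "B4", "B5")
    nets = [
        BipartiteNetwork(m, FUNGI_TO_BACTERIA, sources, targets, w)
        for m in ("CP", "LB")
    ]
    table = fb.qap_all_pairs(nets, FUNGI_TO_BACTERIA, n_perm=200, seed=5)
    assert table["r"].iloc[0] == pytest.approx(1.0)
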