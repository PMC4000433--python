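import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ofdr import PValueSetCollection, bh_step_up, run_simple_bh, run_two_step
from ofdr.core import (
    _second_stage_matrix,
    screening_pvalue_bonferroni,
    screening_pvalue_hochberg,
    second_stage,
    second_stage_rule,
)

from conftest import random_collection, small_pvectors
from reference_impl import (
    bh_reference,
    bonferroni_reference,
    hochberg_reference,
    holm_reference,
)

pvec = st.lists(
    st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=8
).map(np.array)


# ---------------------------------------------------------------------------
# screening p-values


@pytest.mark.parametrize(
    "p, expected",
    [
        ([0.01, 0.04, 0.5, 0.8, 0.9], 0.05),
        ([1.0, 1.0, 1.0], 1.0),
        ([0.3], 0.3),
    ],
)
def test_screening_bonferroni_examples(p, expected):
    assert screening_pvalue_bonferroni(np.array(p)) == pytest.approx(expected)


@pytest.mark.parametrize(
    "p, expected",
    [
        ([0.01, 0.04, 0.5, 0.8, 0.9], 0.05),  # min(5*.01, 4*.04, 3*.5, 2*.8, .9)
        ([0.02, 0.021], 0.021),               # min(2*.02, .021), beats Bonferroni's .04
        ([0.0, 0.5], 0.0),
    ],
)
def test_screening_hochberg_examples(p, expected):
    assert screening_pvalue_hochberg(np.array(p)) == pytest.approx(expected)


@pytest.mark.parametrize("func", [screening_pvalue_bonferroni, screening_pvalue_hochberg])
def test_screening_rejects_invalid_input(func):
    with pytest.raises(ValueError):
        func(np.array([]))
    with pytest.raises(ValueError):
        func(np.array([0.5, 1.2]))
    with pytest.raises(ValueError):
        func(np.array([-0.1]))


@settings(derandomize=True, max_examples=200)
@given(pvec)
def test_hochberg_screening_dominates_bonferroni(p):
    """The Hochberg screening p-value never exceeds the Bonferroni one."""
    assert screening_pvalue_hochberg(p) <= screening_pvalue_bonferroni(p) + 1e-12


# ---------------------------------------------------------------------------
# BH step-up


@pytest.mark.parametrize(
    "p0, alpha, exp_R",
    [
        ([0.001, 0.01, 0.02, 0.04, 0.9], 0.05, 4),
        ([0.9, 0.8, 0.7], 0.05, 0),
        ([0.01], 0.05, 1),
    ],
)
def test_bh_examples(p0, alpha, exp_R):
    res = bh_step_up(np.array(p0), alpha)
    assert res.R == exp_R
    assert res.rejected.sum() == exp_R
    if exp_R:
        assert np.all(res.p0[res.rejected] <= exp_R * alpha / len(p0))


def test_bh_single_pvalue_reduces_to_level_alpha_test():
    assert bh_step_up(np.array([0.049]), 0.05).R == 1
    assert bh_step_up(np.array([0.051]), 0.05).R == 0


def test_bh_invalid_input():
    with pytest.raises(ValueError):
        bh_step_up(np.array([0.1, 0.2]), 1.5)
    with pytest.raises(ValueError):
        bh_step_up(np.array([0.1, 1.2]), 0.05)


@settings(derandomize=True, max_examples=200)
@given(pvec, st.floats(min_value=0.01, max_value=0.2))
def test_bh_matches_reference(p, alpha):
    res = bh_step_up(p, alpha)
    ref_rej, ref_R = bh_reference(p, alpha)
    assert res.R == ref_R
    assert np.array_equal(res.rejected, ref_rej)


@settings(derandomize=True, max_examples=200)
@given(pvec, st.floats(min_value=0.01, max_value=0.2), st.integers(0, 7))
def test_bh_monotone_in_pvalues(p, alpha, which):
    """Componentwise-smaller p-values never reject fewer sets."""
    smaller = p.copy()
    smaller[which % p.size] /= 2.0
    assert bh_step_up(smaller, alpha).R >= bh_step_up(p, alpha).R


# ---------------------------------------------------------------------------
# second stage


@pytest.mark.parametrize(
    "p, level, method, expected",
    [
        ([0.002, 0.018, 0.3], 0.05, "bonferroni", [True, False, False]),
        ([0.002, 0.018, 0.3], 0.05, "holm", [True, True, False]),
        ([0.04, 0.045, 0.049], 0.05, "hochberg", [True, True, True]),
        ([0.04, 0.045, 0.049], 0.05, "holm", [False, False, False]),
    ],
)
def test_second_stage_examples(p, level, method, expected):
    assert second_stage(np.array(p), level, method).tolist() == expected


def test_second_stage_unknown_method():
    with pytest.raises(ValueError):
        second_stage(np.array([0.01]), 0.05, "simes")


def test_second_stage_rule_range():
    rule = second_stage_rule(np.array([0.9, 0.95]), 0.05, "hochberg")
    assert rule.r == 0
    assert second_stage(np.array([0.9, 0.95]), 0.05, "hochberg").sum() == 0


def test_second_stage_matches_references_on_grid():
    """Exhaustive check against the brute-force procedures on small vectors."""
    refs = {
        "bonferroni": bonferroni_reference,
        "holm": holm_reference,
        "hochberg": hochberg_reference,
    }
    for p in small_pvectors(max_len=3):
        for level in (0.01, 0.05, 0.3):
            for method, ref in refs.items():
                got = second_stage(p, level, method)
                assert np.array_equal(got, ref(p, level)), (p, level, method)


def test_second_stage_matches_statsmodels():
    """Independent cross-check against statsmodels' FWER corrections."""
    sm = pytest.importorskip("statsmodels.stats.multitest")
    mapping = {"bonferroni": "bonferroni", "holm": "holm", "hochberg": "simes-hochberg"}
    rng = np.random.default_rng(7)
    for _ in range(200):
        p = rng.uniform(0, 1, rng.integers(1, 8)) ** 2
        level = float(rng.uniform(0.01, 0.5))
        for method, sm_name in mapping.items():
            got = second_stage(p, level, method)
            expected = sm.multipletests(p, alpha=level, method=sm_name)[0]
            assert np.array_equal(got, expected), (p, level, method)


@settings(derandomize=True, max_examples=200)
@given(pvec, st.floats(min_value=0.01, max_value=0.99))
def test_second_stage_rejections_are_nested(p, level):
    bonf = second_stage(p, level, "bonferroni")
    holm = second_stage(p, level, "holm")
    hoch = second_stage(p, level, "hochberg")
    assert np.all(bonf <= holm)
    assert np.all(holm <= hoch)


@settings(derandomize=True, max_examples=100)
@given(st.integers(0, 2**31 - 1))
def test_second_stage_matrix_matches_rowwise(seed):
    rng = np.random.default_rng(seed)
    P = rng.uniform(0, 1, size=(6, 4)) ** 2
    for method in ("bonferroni", "holm", "hochberg"):
        M = _second_stage_matrix(P, 0.1, method)
        for k in range(P.shape[0]):
            assert np.array_equal(M[k], second_stage(P[k], 0.1, method))


def test_second_stage_fwer_under_global_null(rng):
    """P(any rejection) at level l stays below l for independent uniforms."""
    n, level, draws = 5, 0.3, 100_000
    P = rng.uniform(0, 1, size=(draws, n))
    for method in ("bonferroni", "holm", "hochberg"):
        any_rej = _second_stage_matrix(P, level, method).any(axis=1)
        rate = any_rej.mean()
        three_sigma = 3 * np.sqrt(level * (1 - level) / draws)
        assert rate <= level + three_sigma, (method, rate)


# ---------------------------------------------------------------------------
# assembled procedures


def _worked_example():
    return PValueSetCollection(
        [[0.001, 0.5], [0.4, 0.9]], [[1, -1], [1, 1]], labels=["g1", "g2"]
    )


def test_two_step_hand_trace_bonferroni():
    report = run_two_step(_worked_example(), 0.05, "bonferroni")
    assert report.screening.p0.tolist() == [0.002, 0.8]
    assert report.screening.R == 1
    assert report.screening.rejected.tolist() == [True, False]
    assert report.individual_rejected[0].tolist() == [True, False]
    assert report.individual_rejected[1].tolist() == [False, False]
    assert report.direction[0].tolist() == [1, 0]


def test_two_step_hand_trace_holm_matches_bonferroni_here():
    b = run_two_step(_worked_example(), 0.05, "bonferroni")
    h = run_two_step(_worked_example(), 0.05, "holm")
    assert np.array_equal(h.screening.p0, b.screening.p0)
    assert h.screening.R == b.screening.R == 1
    for rb, rh in zip(b.individual_rejected, h.individual_rejected):
        assert np.array_equal(rb, rh)


def test_simple_bh_hand_trace():
    report = run_simple_bh(_worked_example(), 0.05)
    assert report.screening.R == 1
    assert report.individual_rejected[0].tolist() == [True, False]
    assert report.individual_rejected[1].tolist() == [False, False]
    assert report.direction[0].tolist() == [1, 0]


@pytest.mark.parametrize("method", ["bonferroni", "holm", "hochberg"])
def test_all_ones_rejects_nothing(method):
    c = PValueSetCollection([[1.0, 1.0], [1.0, 1.0, 1.0]], [[1, 1], [1, 1, 1]])
    report = run_two_step(c, 0.05, method)
    assert report.screening.R == 0
    assert report.n_individual_rejections == 0
    assert all(np.all(d == 0) for d in report.direction)
    simple = run_simple_bh(c, 0.05)
    assert simple.screening.R == 0


def test_run_two_step_rejects_unknown_method():
    with pytest.raises(ValueError):
        run_two_step(_worked_example(), 0.05, "simple_bh")
    with pytest.raises(ValueError):
        run_two_step(_worked_example(), 0.05, "fisher")


def test_procedures_2_and_3_share_screening(rng):
    """Bonferroni- and Holm-based procedures reject identical sets, always."""
    for ragged in (False, True):
        for _ in range(50):
            c = random_collection(rng, m=12, ragged=ragged)
            b = run_two_step(c, 0.05, "bonferroni")
            h = run_two_step(c, 0.05, "holm")
            assert np.array_equal(b.screening.rejected, h.screening.rejected)
            assert np.array_equal(b.screening.p0, h.screening.p0)


def test_individual_rejections_nested_across_methods(rng):
    for _ in range(50):
        c = random_collection(rng, m=15)
        reports = {m: run_two_step(c, 0.1, m) for m in ("bonferroni", "holm", "hochberg")}
        for rb, rh in zip(
            reports["bonferroni"].individual_rejected, reports["holm"].individual_rejected
        ):
            assert np.all(rb <= rh)
        for rh, rc in zip(
            reports["holm"].individual_rejected, reports["hochberg"].individual_rejected
        ):
            assert np.all(rh <= rc)
        # the Hochberg screening p-value is never larger, so its gene list is a superset
        assert np.all(
            reports["holm"].screening.rejected <= reports["hochberg"].screening.rejected
        )


def test_individual_rejection_implies_set_rejection(rng):
    for _ in range(30):
        c = random_collection(rng, m=10, ragged=True)
        for method in ("bonferroni", "holm", "hochberg"):
            rep = run_two_step(c, 0.05, method)
            for i, rej in enumerate(rep.individual_rejected):
                if rej.any():
                    assert rep.screening.rejected[i]
        simple = run_simple_bh(c, 0.05)
        for i, rej in enumerate(simple.individual_rejected):
            assert simple.screening.rejected[i] == rej.any()


def test_direction_nonzero_iff_rejected(rng):
    for _ in range(30):
        c = random_collection(rng, m=10, ragged=True)  # signs are all +/-1
        for method in ("bonferroni", "holm", "hochberg"):
            rep = run_two_step(c, 0.05, method)
            for rej, d in zip(rep.individual_rejected, rep.direction):
                assert np.array_equal(d != 0, rej)


def test_simple_bh_rejects_at_least_as_many_sets_as_bonferroni(rng):
    # holds for a constant set size: each screened-in set has its smallest
    # p-value below the pooled BH threshold, so pooling can only add sets
    for _ in range(50):
        c = random_collection(rng, m=20, ragged=False)
        two_step = run_two_step(c, 0.05, "bonferroni")
        simple = run_simple_bh(c, 0.05)
        assert simple.screening.R >= two_step.screening.R
        assert np.all(two_step.screening.rejected <= simple.screening.rejected)


def test_simple_bh_can_reject_sets_the_two_step_procedure_keeps():
    # 19 overwhelming sets drive the pooled BH threshold above 0.012, letting
    # the borderline set in, while its screening p-value 5*0.012 > 0.05 keeps
    # it out of the two-step procedure at any R <= m
    p = [[1e-6] * 5 for _ in range(19)] + [[0.012, 1.0, 1.0, 1.0, 1.0]]
    c = PValueSetCollection(p, [[1] * 5] * 20)
    two_step = run_two_step(c, 0.05, "bonferroni")
    simple = run_simple_bh(c, 0.05)
    assert two_step.screening.R == 19
    assert not two_step.screening.rejected[-1]
    assert simple.screening.R == 20
    assert simple.screening.rejected[-1]


def test_zero_sign_rejection_warns_and_declares_no_direction():
    c = PValueSetCollection([[0.0001, 0.9]], [[0, 1]])
    with pytest.warns(UserWarning, match="zero test statistic"):
        report = run_two_step(c, 0.05, "bonferroni")
    assert report.individual_rejected[0].tolist() == [True, False]
    assert report.direction[0].tolist() == [0, 0]


def test_vectorized_procedure_matches_per_set_composition(rng):
    """run_two_step equals screening + BH + per-set second stage done by hand."""
    for method in ("bonferroni", "holm", "hochberg"):
        P = rng.uniform(0, 1, size=(30, 4)) ** 2
        S = rng.choice([-1, 1], size=(30, 4))
        report = run_two_step(PValueSetCollection(P, S), 0.05, method)
        screen_fn = (
            screening_pvalue_hochberg if method == "hochberg" else screening_pvalue_bonferroni
        )
        p0 = np.array([screen_fn(row) for row in P])
        screening = bh_step_up(p0, 0.05)
        assert np.array_equal(report.screening.rejected, screening.rejected)
        if screening.R:
            level = screening.R * 0.05 / 30
            for i in range(30):
                expected = (
                    second_stage(P[i], level, method)
                    if screening.rejected[i]
                    else np.zeros(4, dtype=bool)
                )
                assert np.array_equal(report.individual_rejected[i], expected)


# ---------------------------------------------------------------------------
# containers and tables


def test_collection_validation_errors():
    with pytest.raises(ValueError):
        PValueSetCollection([])
    with pytest.raises(ValueError):
        PValueSetCollection([[0.5, 1.3]])
    with pytest.raises(ValueError):
        PValueSetCollection([[0.5]], [[2]])
    with pytest.raises(ValueError):
        PValueSetCollection([[0.5]], [[1, -1]])
    with pytest.raises(ValueError):
        PValueSetCollection([[0.5]], labels=["a", "b"])


def test_collection_from_long_round_trip():
    import pandas as pd

    frame = pd.DataFrame(
        {
            "set_id": ["g1", "g1", "g2"],
            "hypothesis_id": [1, 2, 1],
            "p_value": [0.01, 0.2, 0.9],
            "statistic_sign": [1, -1, 1],
        }
    )
    c = PValueSetCollection.from_long(frame)
    assert c.labels == ["g1", "g2"]
    assert c.p[0].tolist() == [0.01, 0.2]
    assert c.sign[1].tolist() == [1]
    assert not c.is_uniform


def test_report_tables_and_summary():
    report = run_two_step(_worked_example(), 0.05, "holm")
    sets = report.set_table()
    hyps = report.hypothesis_table()
    assert sets["set_rejected"].tolist() == [True, False]
    assert len(hyps) == 4
    assert "holm" in report.summary()
    assert "sets rejected (R):      1" in report.summary()
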