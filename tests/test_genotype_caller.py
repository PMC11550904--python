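import math

import numpy as np
import pytest

from macall.genotype_caller import (
    bgc_call,
    filter_call,
    het_outcome_prob,
    hom_outcome_prob,
    small_p_pvalue,
)

from .conftest import make_estimate


def naive_outcome_prob(i, j, model, eps, hom_model="conditional"):
    """Direct-product evaluation, independent of the log-space path."""
    n = i + j
    c = math.comb(n, i)
    if model == "het":
        q = 0.5 - eps / 3.0
        return c * q**i * q**j
    a = 1.0 - eps / 3.0 if hom_model == "conditional" else 1.0 - eps
    b = eps / 3.0
    return c * a**i * b**j


def naive_small_p(n_A, n_a, model, eps):
    n = n_A + n_a
    obs = naive_outcome_prob(n_A, n_a, model, eps)
    if obs == 0.0:
        return 0.0
    total = 0.0
    for i in range(n + 1):
        p = naive_outcome_prob(i, n - i, model, eps)
        if p <= obs * (1 + 1e-12):
            total += p
    return min(total, 1.0)


class TestOutcomeProbs:
    @pytest.mark.parametrize(
        "i,j,eps,expected",
        [
            (1, 0, 0.0, 0.5),
            (2, 0, 0.0, 0.25),
            (1, 1, 0.0, 0.5),
        ],
    )
    def test_het_small_cases(self, i, j, eps, expected):
        assert het_outcome_prob(i, j, eps) == pytest.approx(expected, abs=1e-15)

    def test_het_matches_direct_evaluation(self):
        got = het_outcome_prob(5, 5, 0.003)
        assert got == pytest.approx(naive_outcome_prob(5, 5, "het", 0.003), abs=1e-12)

    @pytest.mark.parametrize("n", [1, 5, 30])
    def test_hom_error_free_cases(self, n):
        assert hom_outcome_prob(n, 0, 0.0) == pytest.approx(1.0, abs=1e-15)
        assert hom_outcome_prob(0, 1, 0.0) == 0.0

    def test_hom_matches_direct_evaluation(self):
        # 10 * 0.99^9 * 0.01 with eps/3 = 0.01
        got = hom_outcome_prob(9, 1, 0.03)
        assert got == pytest.approx(10 * 0.99**9 * 0.01, abs=1e-12)

    def test_eps_domain_checked(self):
        with pytest.raises(ValueError):
            het_outcome_prob(1, 1, 0.8)
        with pytest.raises(ValueError):
            hom_outcome_prob(1, 1, -0.1)


class TestSmallPValue:
    def test_balanced_het_is_modal(self):
        assert small_p_pvalue(5, 5, "het", 0.0) == pytest.approx(1.0, abs=1e-12)

    def test_extreme_het_split(self):
        # only (10,0) and (0,10) qualify: p = 2 * 2^-10
        assert small_p_pvalue(10, 0, "het", 0.0) == pytest.approx(
            2.0 * 2.0**-10, abs=1e-15
        )

    def test_pure_hom_reads_give_p_one(self):
        for n in (1, 8, 25):
            assert small_p_pvalue(n, 0, "hom", 0.0) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("eps", [0.0, 1e-3, 1e-2])
    @pytest.mark.parametrize("model", ["het", "hom"])
    def test_agrees_with_enumeration_oracle_small_n(self, model, eps):
        for n in range(1, 16):
            for n_A in range(n + 1):
                got = small_p_pvalue(n_A, n - n_A, model, eps)
                want = naive_small_p(n_A, n - n_A, model, eps)
                assert got == pytest.approx(want, abs=1e-12), (n_A, n - n_A)

    def test_monotone_in_imbalance_het(self):
        for n in (10, 21, 30):
            ps = [small_p_pvalue(k, n - k, "het", 0.0) for k in range(n // 2, n + 1)]
            assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))


class TestBgcCall:
    def test_degenerate_prior_forces_major_hom(self):
        est = make_estimate(freqs=(1.0, 0.0, 0.0))
        call = bgc_call((4, 4, 0, 0), est, min_reads=8)
        assert call.genotype == ("A", "A")
        assert call.posterior == pytest.approx(1.0)

    def test_clear_hom_data_overwhelms_flat_prior(self):
        est = make_estimate(eps=0.01, freqs=(1 / 3, 1 / 3, 1 / 3))
        call = bgc_call((10, 0, 0, 0), est, min_reads=8)
        assert call.genotype == ("A", "A")
        assert call.posterior > 0.99

    def test_depth_threshold(self):
        est = make_estimate()
        call = bgc_call((4, 3, 0, 0), est, min_reads=8)
        assert call.genotype is None
        assert call.depth == 7

    def test_balanced_reads_called_het(self):
        est = make_estimate(eps=0.001, freqs=(0.45, 0.1, 0.45))
        call = bgc_call((6, 6, 0, 0), est, min_reads=8)
        assert call.genotype == ("A", "C")


class TestFilterCall:
    def test_hom_ancestor_clean_reads_kept(self):
        est = make_estimate(eps=0.001)
        call = filter_call((10, 0, 0, 0), ("A", "A"), est)
        assert call.genotype == ("A", "A")
        assert call.p_anc == pytest.approx(1.0, abs=1e-9)

    def test_hom_rejected_balanced_reads_become_het(self):
        est = make_estimate(eps=0.001)
        call = filter_call((6, 6, 0, 0), ("A", "A"), est)
        assert call.p_anc < 0.05  # hom null rejected
        assert call.p_het > 0.5
        assert call.genotype == ("A", "C")

    def test_single_supporting_read_vetoes_het(self):
        est = make_estimate(eps=0.001)
        call = filter_call((11, 1, 0, 0), ("A", "A"), est)
        assert call.p_anc < 0.05
        assert call.genotype is None

    def test_het_ancestor_balanced_kept(self):
        est = make_estimate(eps=0.001, freqs=(0.25, 0.5, 0.25))
        call = filter_call((5, 6, 0, 0), ("A", "C"), est)
        assert call.genotype == ("A", "C")

    def test_het_ancestor_pure_reads_downgraded_to_hom(self):
        est = make_estimate(eps=0.001, freqs=(0.25, 0.5, 0.25))
        call = filter_call((12, 0, 0, 0), ("A", "C"), est)
        assert call.p_anc < 0.025
        assert call.genotype == ("A", "A")

    def test_het_ancestor_mixed_reads_rejected_to_no_call(self):
        est = make_estimate(eps=0.001, freqs=(0.25, 0.5, 0.25))
        call = filter_call((11, 1, 0, 0), ("A", "C"), est)
        assert call.genotype is None

    def test_depth_below_minimum_short_circuits(self):
        est = make_estimate()
        call = filter_call((4, 3, 0, 0), ("A", "A"), est, min_reads=8)
        assert call.genotype is None and call.p_anc is None

    def test_missing_ancestor_is_contract_violation(self):
        with pytest.raises(ValueError):
            filter_call((10, 0, 0, 0), None, make_estimate())

    def test_never_emits_het_with_single_read_support(self, rng):
        est = make_estimate(eps=0.005)
        for _ in range(200):
            nA = int(rng.integers(0, 25))
            nC = int(rng.integers(0, 25))
            call = filter_call((nA, nC, 0, 0), ("A", "A"), est)
            if call.genotype == ("A", "C"):
                assert nA >= 2 and nC >= 2

    def test_complement_hom_model_switch(self):
        est = make_estimate(eps=0.01)
        p_default = filter_call((18, 2, 0, 0), ("A", "A"), est).p_anc
        p_comp = filter_call(
            (18, 2, 0, 0), ("A", "A"), est, hom_model="complement"
        ).p_anc
        assert p_default != p_comp
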