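import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from macall.site_model import (
    estimate_site,
    estimate_sites,
    pick_alleles,
    polymorphism_test,
)

from .conftest import make_site


def grid_oracle(counts, p_mm_grid, eps_grid):
    """Dense grid search over (P_Mm, eps) with P_MM = 1 - P_Mm, P_mm = 0.

    Independent of the EM implementation: evaluates the mixture
    likelihood directly at every grid point and returns the argmax.
    """
    counts = np.asarray(counts, dtype=float)
    pooled = counts.sum(axis=0)
    order = np.argsort(-pooled, kind="stable")
    n_M, n_m = counts[:, order[0]], counts[:, order[1]]
    n_o = counts.sum(axis=1) - n_M - n_m
    def xlog(x, v):  # 0 * log(0) := 0, term by term
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(x > 0, x * np.log(v), 0.0)

    best = (-np.inf, None, None)
    for p_mm in p_mm_grid:
        for eps in eps_grid:
            ll_MM = xlog(n_M, 1 - eps) + xlog(n_m + n_o, eps / 3)
            ll_Mm = xlog(n_M + n_m, 0.5 - eps / 3) + xlog(n_o, eps / 3)
            mix = (1 - p_mm) * np.exp(ll_MM) + p_mm * np.exp(ll_Mm)
            if (mix <= 0).any():
                continue
            ll = np.log(mix).sum()
            if ll > best[0]:
                best = (ll, p_mm, eps)
    return best


class TestPickAlleles:
    @pytest.mark.parametrize(
        "pooled,expected",
        [
            ((100, 0, 7, 0), ("A", "G")),
            ((50, 50, 0, 0), ("A", "C")),  # tie broken A<C<G<T
            ((12, 0, 0, 0), ("A", None)),
            ((0, 3, 3, 9), ("T", "C")),
        ],
    )
    def test_rank_and_tiebreak(self, pooled, expected):
        site = make_site([pooled])
        assert pick_alleles(site) == expected

    def test_no_reads_raises(self):
        with pytest.raises(ValueError):
            pick_alleles(make_site([(0, 0, 0, 0)]))


class TestEstimateSite:
    def test_perfect_monomorphic(self):
        site = make_site([(20, 0, 0, 0)] * 14)
        est = estimate_site(site)
        assert est.eps_hat == pytest.approx(0.0, abs=1e-9)
        assert est.geno_freqs[0] == pytest.approx(1.0, abs=1e-9)
        assert est.lrt_stat == pytest.approx(0.0, abs=1e-6)
        assert not est.is_polymorphic

    def test_half_het_configuration_matches_grid_oracle(self):
        counts = [(20, 0, 0, 0)] * 7 + [(10, 10, 0, 0)] * 7
        est = estimate_site(make_site(counts))
        _, p_mm_star, eps_star = grid_oracle(
            counts, np.linspace(0, 1, 1001), np.linspace(0, 0.02, 81)
        )
        assert est.geno_freqs[1] == pytest.approx(p_mm_star, abs=1e-3)
        assert est.eps_hat == pytest.approx(eps_star, abs=1e-3)
        assert est.geno_freqs[1] == pytest.approx(0.5, abs=1e-3)

    def test_single_error_read_gives_small_positive_eps(self):
        counts = [(20, 0, 0, 0)] * 13 + [(19, 0, 1, 0)]
        est = estimate_site(make_site(counts))
        assert est.eps_hat > 0
        assert est.polymorphic_p > 0.05

    def test_deterministic(self):
        site = make_site([(9, 3, 1, 0)] * 4 + [(5, 5, 0, 0)] * 3)
        a, b = estimate_site(site), estimate_site(site)
        assert a == b  # bit-identical floats

    @given(
        st.lists(
            st.tuples(*[st.integers(0, 30)] * 4), min_size=2, max_size=8
        ).filter(lambda ls: sum(map(sum, ls)) > 0)
    )
    @settings(max_examples=60, deadline=None)
    def test_full_model_never_below_mono(self, counts):
        est = estimate_site(make_site(counts))
        assert est.loglik_full >= est.loglik_mono - 1e-9
        assert est.lrt_stat >= -1e-9
        assert 0.0 <= est.eps_hat <= 0.75
        assert sum(est.geno_freqs) == pytest.approx(1.0, abs=1e-9)

    def test_eps_recovery_on_model_data(self, rng):
        S, L, depth, eps = 300, 14, 20, 0.005
        counts = rng.multinomial(
            depth, [1 - eps, eps / 3, eps / 3, eps / 3], size=(S, L)
        )
        est = estimate_sites(counts)
        mcse = est.eps.std() / np.sqrt(S)
        assert abs(est.eps.mean() - eps) < 3 * mcse


class TestPolymorphismTest:
    def test_null_data_gives_p_one(self):
        est = estimate_site(make_site([(15, 0, 0, 0)] * 6))
        assert polymorphism_test(est) == pytest.approx(1.0, abs=1e-6)

    def test_clean_het_site_is_highly_significant(self):
        counts = [(20, 0, 0, 0)] * 7 + [(10, 10, 0, 0)] * 7
        est = estimate_site(make_site(counts))
        assert est.polymorphic_p < 1e-6
        assert est.is_polymorphic

    def test_five_percent_boundary_statistic(self):
        from .conftest import make_estimate

        # LRT at the 5% critical value of chi-square(2) sits on the boundary
        est = make_estimate(lrt=5.991464547107979)
        assert polymorphism_test(est) == pytest.approx(0.05, rel=1e-9)
        assert polymorphism_test(make_estimate(lrt=0.0)) == 1.0
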