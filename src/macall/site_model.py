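"""Per-site maximum-likelihood genotype-frequency and error-rate estimation.

At each site the sample of MA lines is modelled as a mixture over the
three genotypes formed by the site's two alleles (major M, minor m).
Given genotype g and per-read error rate eps, a read falls in the four
nucleotide categories with probabilities

* MM:  P(M) = 1 - eps,          P(each other nt) = eps / 3
* Mm:  P(M) = P(m) = 1/2 - eps/3, P(each other nt) = eps / 3
* mm:  symmetric to MM.

The heterozygote allele probability 1/2 - eps/3 arises because a read
drawn from either chromosome is mis-read to one of the three other
nucleotides with probability eps (spread evenly), so
P(M) = (1-eps)/2 + (eps/3)/2.

The free parameters (P_MM, P_Mm, P_mm, eps) are fitted by EM over two
latent variables: each line's genotype and each read's error indicator.
Both E-steps are closed form, and the eps update is the expected error
fraction, so the fit is monotone and deterministic.  The monomorphic
null (best single homozygous genotype frequency fixed at 1) has a
closed-form eps MLE; the likelihood-ratio statistic against it, referred
to a chi-square with 2 degrees of freedom, flags significantly
polymorphic sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2

from .io_formats import NUCLEOTIDES, SiteCounts

EPS_MAX = 0.75
_EM_TOL = 1e-10
_EM_MAX_ITER = 1000


@dataclass(frozen=True)
class SiteEstimate:
    """Fitted per-site model: alleles, genotype frequencies, error rate."""

    major_nt: str
    minor_nt: str | None
    eps_hat: float
    geno_freqs: tuple[float, float, float]  # (P_MM, P_Mm, P_mm)
    loglik_full: float
    loglik_mono: float
    lrt_stat: float
    polymorphic_p: float

    @property
    def is_polymorphic(self) -> bool:
        return self.polymorphic_p < 0.05


@dataclass
class BatchEstimates:
    """Vectorised :class:`SiteEstimate` fields over a batch of sites.

    ``valid`` is False for sites with zero total reads, which carry no
    estimate.  ``major`` / ``minor`` are nucleotide codes (0..3); minor
    is -1 at monomorphic sites.
    """

    major: np.ndarray
    minor: np.ndarray
    eps: np.ndarray
    geno_freqs: np.ndarray  # (S, 3)
    loglik_full: np.ndarray
    loglik_mono: np.ndarray
    lrt: np.ndarray
    polymorphic_p: np.ndarray
    valid: np.ndarray

    def site(self, i: int) -> SiteEstimate | None:
        if not self.valid[i]:
            return None
        minor = None if self.minor[i] < 0 else NUCLEOTIDES[self.minor[i]]
        return SiteEstimate(
            NUCLEOTIDES[self.major[i]],
            minor,
            float(self.eps[i]),
            tuple(float(x) for x in self.geno_freqs[i]),
            float(self.loglik_full[i]),
            float(self.loglik_mono[i]),
            float(self.lrt[i]),
            float(self.polymorphic_p[i]),
        )


def pick_alleles(site: SiteCounts) -> tuple[str, str | None]:
    """Major/minor allele by pooled counts, ties broken A<C<G<T."""
    pooled = np.array(site.pooled())
    if pooled.sum() == 0:
        raise ValueError("no reads at site; no alleles to pick")
    major, minor = _pick_alleles_batch(pooled[None, :])
    minor_nt = None if minor[0] < 0 else NUCLEOTIDES[minor[0]]
    return NUCLEOTIDES[major[0]], minor_nt


def _pick_alleles_batch(pooled: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised allele picking from pooled (S, 4) counts.

    Ranks by count with the fixed nucleotide order A<C<G<T breaking
    ties; minor is -1 where only one nucleotide has reads.
    """
    # stable argsort on (-count, nucleotide index)
    order = np.argsort(-pooled, axis=1, kind="stable")
    major = order[:, 0]
    minor = order[:, 1].copy()
    minor_count = np.take_along_axis(pooled, minor[:, None], axis=1)[:, 0]
    minor[minor_count == 0] = -1
    return major, minor


def _genotype_logliks(
    n_M: np.ndarray, n_m: np.ndarray, n_o: np.ndarray, eps: np.ndarray
) -> np.ndarray:
    """Per-line log P(counts | g, eps) without the multinomial coefficient.

    Shapes: counts (S, L), eps (S,); returns (S, L, 3) over (MM, Mm, mm).
    Zero counts contribute nothing even when their category probability
    is zero (0 * log 0 := 0), so eps = 0 is handled exactly.
    """
    eps = eps[:, None]
    with np.errstate(divide="ignore"):
        log_err = np.log(eps / 3.0)
        log_hom = np.log1p(-eps)
        log_het = np.log(0.5 - eps / 3.0)

    def xlogy(x, logy):
        with np.errstate(invalid="ignore"):
            return np.where(x > 0, x * logy, 0.0)

    ll_MM = xlogy(n_M, log_hom) + xlogy(n_m + n_o, log_err)
    ll_Mm = xlogy(n_M + n_m, log_het) + xlogy(n_o, log_err)
    ll_mm = xlogy(n_m, log_hom) + xlogy(n_M + n_o, log_err)
    return np.stack([ll_MM, ll_Mm, ll_mm], axis=2)


def _multinomial_coef(counts: np.ndarray) -> np.ndarray:
    """Sum over lines of log multinomial coefficients, shape (S,)."""
    n = counts.sum(axis=2)
    return (gammaln(n + 1) - gammaln(counts + 1).sum(axis=2)).sum(axis=1)


def estimate_sites(counts: np.ndarray, major=None, minor=None) -> BatchEstimates:
    """Fit the site model to every site of a ``(S, L, 4)`` count array.

    All sites are iterated simultaneously; converged sites drop out of
    the working set.  The fit is deterministic: fixed initialisation
    (uniform genotype frequencies, eps = 0.01) and no randomness.
    """
    counts = np.asarray(counts, dtype=np.float64)
    S = counts.shape[0]
    pooled = counts.sum(axis=1)
    valid = pooled.sum(axis=1) > 0
    if major is None or minor is None:
        major, minor = _pick_alleles_batch(
            np.where(valid[:, None], pooled, 1)
        )
        minor = np.where(valid, minor, -1)
        major = np.where(valid, major, 0)

    take = lambda idx: np.take_along_axis(
        counts, np.clip(idx, 0, 3)[:, None, None], axis=2
    )[:, :, 0]
    n_M = take(major)
    n_m = np.where((minor >= 0)[:, None], take(minor), 0.0)
    depth = counts.sum(axis=2)
    n_o = depth - n_M - n_m

    eps = np.full(S, 0.01)
    freqs = np.full((S, 3), 1.0 / 3.0)
    ll = np.full(S, -np.inf)
    active = valid.copy()

    for _ in range(_EM_MAX_ITER):
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        gl = _genotype_logliks(n_M[idx], n_m[idx], n_o[idx], eps[idx])
        with np.errstate(divide="ignore"):
            log_post = gl + np.log(freqs[idx])[:, None, :]
        line_ll = logsumexp(log_post, axis=2)
        new_ll = line_ll.sum(axis=1)
        resp = np.exp(log_post - line_ll[:, :, None])

        # expected error reads per line given each genotype
        e = eps[idx][:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            w_het = np.where(e > 0, (e / 6.0) / (0.5 - e / 3.0), 0.0)
        err_MM = n_m[idx] + n_o[idx]
        err_Mm = n_o[idx] + (n_M[idx] + n_m[idx]) * w_het
        err_mm = n_M[idx] + n_o[idx]
        exp_err = (
            resp[:, :, 0] * err_MM + resp[:, :, 1] * err_Mm + resp[:, :, 2] * err_mm
        ).sum(axis=1)

        freqs[idx] = resp.mean(axis=1)
        total = depth[idx].sum(axis=1)
        eps[idx] = np.clip(exp_err / np.maximum(total, 1.0), 0.0, EPS_MAX)

        done = new_ll - ll[idx] < _EM_TOL
        ll[idx] = new_ll
        active[idx[done]] = False

    coef = _multinomial_coef(counts)
    ll_full = ll + coef

    # monomorphic null: best single homozygous genotype at frequency 1
    total = depth.sum(axis=1)
    ll_mono = np.full(S, -np.inf)
    mono_which = np.zeros(S, dtype=np.int8)  # 0 -> MM corner, 2 -> mm corner
    mono_eps = np.zeros(S)
    for which, (hom_allele_counts, err_counts) in (
        (0, (n_M, n_m + n_o)),
        (2, (n_m, n_M + n_o)),
    ):
        errs = err_counts.sum(axis=1)
        eps_mle = np.clip(errs / np.maximum(total, 1.0), 0.0, EPS_MAX)
        with np.errstate(divide="ignore"):
            lh = np.where(eps_mle < 1, np.log1p(-eps_mle), -np.inf)
            le = np.where(eps_mle > 0, np.log(eps_mle / 3.0), -np.inf)
        hits = hom_allele_counts.sum(axis=1)
        with np.errstate(invalid="ignore"):
            ll_h = (
                np.where(hits > 0, hits * lh, 0.0)
                + np.where(errs > 0, errs * le, 0.0)
                + coef
            )
        better = ll_h > ll_mono
        mono_which[better] = which
        mono_eps[better] = eps_mle[better]
        ll_mono = np.maximum(ll_mono, ll_h)

    # the mono corner lies inside the full parameter space; if EM stalled
    # below it, adopt the corner so the models stay properly nested
    stalled = ll_mono > ll_full
    if stalled.any():
        ll_full[stalled] = ll_mono[stalled]
        eps[stalled] = mono_eps[stalled]
        freqs[stalled] = 0.0
        freqs[stalled, mono_which[stalled]] = 1.0

    lrt = np.clip(2.0 * (ll_full - ll_mono), 0.0, None)
    p = chi2.sf(lrt, df=2)
    ll_full[~valid] = np.nan
    ll_mono[~valid] = np.nan
    lrt[~valid] = np.nan
    p[~valid] = np.nan
    return BatchEstimates(
        major=major,
        minor=minor,
        eps=eps,
        geno_freqs=freqs,
        loglik_full=ll_full,
        loglik_mono=ll_mono,
        lrt=lrt,
        polymorphic_p=p,
        valid=valid,
    )


def estimate_site(site: SiteCounts) -> SiteEstimate:
    """Fit the genotype-frequency/error model at a single site."""
    counts = np.asarray(site.counts, dtype=np.float64)[None, :, :]
    if counts.sum() == 0:
        raise ValueError("all-zero counts at every line; no estimate")
    batch = estimate_sites(counts)
    est = batch.site(0)
    assert est is not None
    return est


def polymorphism_test(est: SiteEstimate) -> float:
    """Upper-tail chi-square(2) p-value of the polymorphism LRT."""
    return float(chi2.sf(max(est.lrt_stat, 0.0), df=2))
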