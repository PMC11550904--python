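"""Per-line Bayesian genotype calling and the exact binomial filter.

Calls are made in two stages.  First, each line's genotype posterior is
computed over (MM, Mm, mm) from its read counts, the site's fitted
genotype frequencies (used as priors) and the site's error-rate
estimate.  Second, calls at bi-allelic sites are filtered by a
two-tailed exact binomial goodness-of-fit test against the inferred
ancestral genotype, using the method of small p-values: the p-value is
the sum of the probabilities of every outcome no more probable than the
observed one, which is conservative, so no multiple-testing correction
is applied.

Under a heterozygous null the probability of observing allele counts
(n_A, n_a) is

    C(n_A + n_a, n_A) * (1/2 - eps/3)^n_A * (1/2 - eps/3)^n_a

and under a homozygous-A null

    C(n_A + n_a, n_A) * (1 - eps/3)^n_A * (eps/3)^n_a

with eps the site's error-rate estimate.  An alternative homozygous
success probability (1 - eps) is available as ``hom_model="complement"``
for sensitivity analysis; the default follows the first form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .site_model import EPS_MAX, SiteEstimate

#: sentinel genotype for lines that cannot be called
NO_CALL = None

#: relative tolerance for probability ties in the small-p qualifying set;
#: ties are included, which can only enlarge the p-value (conservative)
TIE_RTOL = 1e-12


@dataclass(frozen=True)
class GenotypeCall:
    """One line's filtered genotype at a site (or no-call)."""

    line_id: str
    genotype: tuple[str, str] | None  # sorted nucleotide pair, None = NO_CALL
    depth: int
    posterior: float | None = None
    p_anc: float | None = None
    p_het: float | None = None


def _check_eps(eps_hat: float) -> None:
    if not 0.0 <= eps_hat <= EPS_MAX:
        raise ValueError(f"error rate {eps_hat} outside [0, {EPS_MAX}]")


def het_outcome_prob(i: int, j: int, eps_hat: float) -> float:
    """P(i reads of A, j of a | genotype Aa), computed in log space."""
    _check_eps(eps_hat)
    q = 0.5 - eps_hat / 3.0
    n = i + j
    if n == 0:
        return 1.0
    log_c = math.lgamma(n + 1) - math.lgamma(i + 1) - math.lgamma(j + 1)
    return math.exp(log_c + n * math.log(q))


def hom_outcome_prob(
    i: int, j: int, eps_hat: float, hom_model: str = "conditional"
) -> float:
    """P(i reads of A, j of a | genotype AA), computed in log space."""
    _check_eps(eps_hat)
    a, b = _hom_probs(eps_hat, hom_model)
    n = i + j
    if n == 0:
        return 1.0
    if b == 0.0 and j > 0:
        return 0.0
    log_c = math.lgamma(n + 1) - math.lgamma(i + 1) - math.lgamma(j + 1)
    log_b = j * math.log(b) if j > 0 else 0.0
    return math.exp(log_c + i * math.log(a) + log_b)


def _hom_probs(eps_hat: float, hom_model: str) -> tuple[float, float]:
    if hom_model == "conditional":
        return 1.0 - eps_hat / 3.0, eps_hat / 3.0
    if hom_model == "complement":
        return 1.0 - eps_hat, eps_hat / 3.0
    raise ValueError(f"unknown hom_model {hom_model!r}")


def _outcome_logprobs(n: int, model: str, eps_hat: float, hom_model: str):
    """Log P(i, n-i | model) for i = 0..n, -inf where impossible."""
    i = np.arange(n + 1)
    log_c = gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
    if model == "het":
        q = 0.5 - eps_hat / 3.0
        return log_c + n * math.log(q)
    if model != "hom":
        raise ValueError(f"unknown model {model!r}")
    a, b = _hom_probs(eps_hat, hom_model)
    with np.errstate(divide="ignore"):
        la = math.log(a)
        lb = math.log(b) if b > 0 else -math.inf
    with np.errstate(invalid="ignore"):
        lp = log_c + i * la + np.where(n - i > 0, (n - i) * lb, 0.0)
    return lp


def small_p_pvalue(
    n_A: int,
    n_a: int,
    model: str,
    eps_hat: float,
    hom_model: str = "conditional",
) -> float:
    """Two-tailed exact p-value by the method of small p-values.

    Sums P(i, j) over every outcome with i + j = n_A + n_a whose
    probability does not exceed that of the observed outcome (ties
    included, within relative tolerance :data:`TIE_RTOL`).
    """
    _check_eps(eps_hat)
    n = n_A + n_a
    if n < 1:
        raise ValueError("need at least one allele read")
    lp = _outcome_logprobs(n, model, eps_hat, hom_model)
    lp_obs = lp[n_A]
    if lp_obs == -math.inf:
        # the observed outcome has probability zero; only other
        # zero-probability outcomes qualify, so p = 0
        return 0.0
    qualify = lp <= lp_obs + math.log1p(TIE_RTOL)
    p = float(np.exp(lp[qualify]).sum())
    return min(max(p, 0.0), 1.0)


def bgc_call(
    line_counts,
    est: SiteEstimate,
    min_reads: int = 8,
    line_id: str = "",
) -> GenotypeCall:
    """Posterior genotype call for one line from its A/C/G/T counts.

    The posterior over (MM, Mm, mm) is proportional to the site's fitted
    genotype frequency times the multinomial read likelihood.  Lines
    with fewer than ``min_reads`` total reads are not called.
    """
    counts = np.asarray(line_counts, dtype=float)
    depth = int(counts.sum())
    if depth < min_reads:
        return GenotypeCall(line_id, NO_CALL, depth)
    from .io_formats import NUC_INDEX

    M = NUC_INDEX[est.major_nt]
    m = NUC_INDEX[est.minor_nt] if est.minor_nt is not None else None
    n_M = counts[M]
    n_m = counts[m] if m is not None else 0.0
    n_o = depth - n_M - n_m
    eps = est.eps_hat

    def xlogy(x, y):
        if x == 0:
            return 0.0
        return x * (math.log(y) if y > 0 else -math.inf)

    ll = np.array(
        [
            xlogy(n_M, 1 - eps) + xlogy(n_m + n_o, eps / 3),
            xlogy(n_M + n_m, 0.5 - eps / 3) + xlogy(n_o, eps / 3),
            xlogy(n_m, 1 - eps) + xlogy(n_M + n_o, eps / 3),
        ]
    )
    with np.errstate(divide="ignore"):
        log_prior = np.log(np.asarray(est.geno_freqs))
    if est.minor_nt is None:
        log_prior = np.array([0.0, -math.inf, -math.inf])
    log_post = log_prior + ll
    if not np.isfinite(log_post).any():
        return GenotypeCall(line_id, NO_CALL, depth)
    log_post -= logsumexp(log_post)
    g = int(np.argmax(log_post))
    genotypes = [
        (est.major_nt, est.major_nt),
        tuple(sorted((est.major_nt, est.minor_nt or est.major_nt))),
        (est.minor_nt or est.major_nt,) * 2,
    ]
    return GenotypeCall(
        line_id, genotypes[g], depth, posterior=float(np.exp(log_post[g]))
    )


def filter_call(
    line_counts,
    anc: tuple[str, str],
    est: SiteEstimate,
    alpha_het: float = 0.025,
    alpha_hom: float = 0.05,
    min_reads: int = 8,
    hom_model: str = "conditional",
    line_id: str = "",
) -> GenotypeCall:
    """Exact-binomial filtered genotype call against the ancestral null.

    The null that the line kept the ancestral genotype is tested first.
    With a heterozygous ancestor, rejection downgrades the call to a
    homozygote only when every read in the line is one nucleotide.  With
    a homozygous ancestor, rejection triggers a second, heterozygous
    null; a heterozygote is emitted only when that null stands and both
    alleles carry at least two reads.  Otherwise the line is uncalled.
    """
    if anc is None:
        raise ValueError("ancestral genotype required")
    counts = np.asarray(line_counts, dtype=int)
    depth = int(counts.sum())
    if depth < min_reads:
        return GenotypeCall(line_id, NO_CALL, depth)
    from .io_formats import NUC_INDEX, NUCLEOTIDES

    alleles = [est.major_nt] + ([est.minor_nt] if est.minor_nt else [])
    anc = tuple(sorted(anc))
    if anc[0] != anc[1]:  # heterozygous ancestor Aa
        n_A = int(counts[NUC_INDEX[anc[0]]])
        n_a = int(counts[NUC_INDEX[anc[1]]])
        if n_A + n_a == 0:
            return GenotypeCall(line_id, NO_CALL, depth)
        p_het = small_p_pvalue(n_A, n_a, "het", est.eps_hat, hom_model)
        if p_het >= alpha_het:
            return GenotypeCall(line_id, anc, depth, p_anc=p_het, p_het=p_het)
        nonzero = np.nonzero(counts)[0]
        if len(nonzero) == 1:  # all reads one nucleotide
            nt = NUCLEOTIDES[nonzero[0]]
            return GenotypeCall(line_id, (nt, nt), depth, p_anc=p_het, p_het=p_het)
        return GenotypeCall(line_id, NO_CALL, depth, p_anc=p_het, p_het=p_het)

    # homozygous ancestor AA; the alternative allele a is the site's
    # other allele (if the site is monomorphic there is none: n_a = 0)
    A = anc[0]
    others = [x for x in alleles if x != A]
    a = others[0] if others else None
    n_A = int(counts[NUC_INDEX[A]])
    n_a = int(counts[NUC_INDEX[a]]) if a is not None else 0
    if n_A + n_a == 0:
        return GenotypeCall(line_id, NO_CALL, depth)
    p_hom = small_p_pvalue(n_A, n_a, "hom", est.eps_hat, hom_model)
    if p_hom >= alpha_hom:
        return GenotypeCall(line_id, anc, depth, p_anc=p_hom)
    if a is None:
        return GenotypeCall(line_id, NO_CALL, depth, p_anc=p_hom)
    p_het = small_p_pvalue(n_A, n_a, "het", est.eps_hat, hom_model)
    if p_het >= alpha_het and n_A >= 2 and n_a >= 2:
        gt = tuple(sorted((A, a)))
        return GenotypeCall(line_id, gt, depth, p_anc=p_hom, p_het=p_het)
    return GenotypeCall(line_id, NO_CALL, depth, p_anc=p_hom, p_het=p_het)
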