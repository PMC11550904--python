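"""Mutation-rate estimation and mutation spectra.

The per-site per-generation per-line mutation rate is

    mu = m / (2 * N * T * g)

with m candidate mutations over N callable sites in T diploid lines
after a mean of g generations; the 2 counts the two chromosome copies
per line.  Treating m as Poisson gives the standard error

    SE = sqrt(mu / (2 * N * T * g))  =  mu / sqrt(m).

Conditional (per-ancestral-nucleotide) rates use the callable-site
count N_X of sites whose ancestral nucleotide is X; the Ts/Tv ratio and
the AT bias are ratios of sums of these conditional rates.  Under a
uniform model (every nucleotide equally likely to mutate to any other)
Ts/Tv = 4/8 = 0.5, the null against which transitional bias is judged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .mutation_finder import CandidateMutation

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
MUTATION_TYPES = [
    (x, y) for x in "ACGT" for y in "ACGT" if x != y
]


def round_sig(x: float, digits: int = 3) -> float:
    """Round to ``digits`` significant figures (display convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1)


@dataclass(frozen=True)
class RateEstimate:
    m: int
    N: int
    T: int
    g: float
    mu: float
    se: float

    def __str__(self) -> str:
        return f"{round_sig(self.mu):.3g} +/- {round_sig(self.se):.3g}"


@dataclass(frozen=True)
class SpectrumEstimate:
    """Twelve conditional rates plus the Ts/Tv and AT-bias summaries."""

    counts: Mapping[tuple[str, str], int]
    callable_by_nt: Mapping[str, int]
    rates: Mapping[tuple[str, str], float]
    ts_tv: float  # NaN when no transversions observed
    at_bias: float  # NaN when no A/T -> G/C mutations observed


def mutation_rate(m: int, N: int, T: int, g: float) -> RateEstimate:
    """Point estimate and Poisson SE of mu = m / (2 N T g)."""
    if N <= 0 or T <= 0 or g <= 0:
        raise ValueError("N, T and g must all be positive")
    if m < 0:
        raise ValueError("m must be non-negative")
    denom = 2.0 * N * T * g
    mu = m / denom
    se = math.sqrt(mu / denom)
    return RateEstimate(m=m, N=N, T=T, g=g, mu=mu, se=se)


def pairwise_rate(m_ij: int, N_ij: int, T: int, g: float) -> RateEstimate:
    """Rate for a time-point pair: m and N restricted to sites callable
    at both time points and candidates found at both."""
    return mutation_rate(m_ij, N_ij, T, g)


def conditional_spectrum(
    candidates: Sequence[CandidateMutation],
    callable_base_counts: Mapping[str, int],
    T: int,
    g: float,
) -> SpectrumEstimate:
    """Conditional rates per ancestral nucleotide, pooled over time points.

    ``callable_base_counts`` gives N_X per ancestral nucleotide X with
    multiplicity over time points (a site callable at k time points
    contributes k), mirroring the pooled candidate numerator.
    """
    counts = {t: 0 for t in MUTATION_TYPES}
    for c in candidates:
        counts[(c.ancestral_nt, c.mutant_nt)] += 1
    rates: dict[tuple[str, str], float] = {}
    for (x, y), m in counts.items():
        n_x = callable_base_counts.get(x, 0)
        if n_x <= 0:
            if m > 0:
                raise ValueError(f"mutations from {x} but no callable {x} sites")
            rates[(x, y)] = math.nan
            continue
        rates[(x, y)] = m / (2.0 * n_x * T * g)
    ts = sum(
        rates[t] for t in TRANSITIONS if not math.isnan(rates[t])
    )
    tv = sum(
        rates[t]
        for t in MUTATION_TYPES
        if t not in TRANSITIONS and not math.isnan(rates[t])
    )
    gc_to_at = [("G", "A"), ("G", "T"), ("C", "A"), ("C", "T")]
    at_to_gc = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
    num = sum(rates[t] for t in gc_to_at if not math.isnan(rates[t]))
    den = sum(rates[t] for t in at_to_gc if not math.isnan(rates[t]))
    ts_tv = ts / tv if tv > 0 else math.nan
    at_bias = num / den if den > 0 else math.nan
    return SpectrumEstimate(
        counts=counts,
        callable_by_nt=dict(callable_base_counts),
        rates=rates,
        ts_tv=ts_tv,
        at_bias=at_bias,
    )


@dataclass(frozen=True)
class MeanRate:
    mu: float
    se: float
    n_estimates: int


def mean_rate(estimates: Iterable[RateEstimate]) -> MeanRate:
    """Arithmetic mean of rate estimates; SE = sqrt(sum se_i^2) / k."""
    ests = list(estimates)
    if not ests:
        raise ValueError("no estimates to average")
    k = len(ests)
    mu = sum(e.mu for e in ests) / k
    se = math.sqrt(sum(e.se**2 for e in ests)) / k
    return MeanRate(mu=mu, se=se, n_estimates=k)
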