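"""Removal of potentially problematic sites.

Four independent per-site filters protect mutation identification from
known failure modes: sites with credible third/fourth alleles (the
two-allele model cannot represent them), sites whose total pooled
coverage is atypical (collapsed repeats, deletions), sites with a high
error-rate estimate, and sites inside repeat-masked intervals.  A
site's verdict accumulates every failed filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import binom

from .io_formats import RegionMask, SiteCounts
from .site_model import BatchEstimates, SiteEstimate

MULTIALLELIC = "MULTIALLELIC"
COVERAGE = "COVERAGE"
ERROR_RATE = "ERROR_RATE"
REPEAT = "REPEAT"

#: floor applied to the error-rate estimate in the multi-allelic test so
#: that a zero estimate cannot make any third-allele read "significant"
EPS_FLOOR = 1e-4


@dataclass(frozen=True)
class FilterVerdict:
    scaffold: str
    position: int
    flags: frozenset[str]

    @property
    def passed(self) -> bool:
        return not self.flags


@dataclass
class FilterConfig:
    min_total_coverage: int = 40
    max_total_coverage: int = 400
    max_error_rate: float = 0.01
    multiallelic_alpha: float = 0.05
    multiallelic_min_reads: int = 6


def detect_multiallelic(
    site: SiteCounts,
    est: SiteEstimate,
    min_reads: int = 6,
    alpha: float = 0.05,
) -> bool:
    """Flag sites where a third (or fourth) allele exceeds error expectation.

    Reads are pooled over lines with at least ``min_reads`` reads; the
    third- and fourth-ranked nucleotide counts are each tested with a
    one-sided binomial test against success probability eps/3 (eps
    floored at :data:`EPS_FLOOR`).
    """
    counts = np.asarray(site.counts)
    eligible = counts.sum(axis=1) >= min_reads
    if not eligible.any():
        return False
    pooled = counts[eligible].sum(axis=0)
    return bool(
        _multiallelic_from_pooled(
            pooled[None, :], np.array([est.eps_hat]), min_reads, alpha
        )[0]
    )


def _multiallelic_from_pooled(
    pooled: np.ndarray, eps: np.ndarray, min_reads: int, alpha: float
) -> np.ndarray:
    """Vectorised third/fourth-allele test on pooled (S, 4) counts."""
    total = pooled.sum(axis=1)
    ranked = -np.sort(-pooled, axis=1)
    p_err = np.maximum(eps, EPS_FLOOR) / 3.0
    flagged = np.zeros(len(total), dtype=bool)
    for rank in (2, 3):
        k = ranked[:, rank]
        has = k > 0
        if has.any():
            pv = binom.sf(k[has] - 1, total[has], p_err[has])
            idx = np.nonzero(has)[0]
            flagged[idx[pv < alpha]] = True
    return flagged


def coverage_filter(site: SiteCounts, min_total: int, max_total: int) -> bool:
    """Flag iff total pooled depth falls outside [min_total, max_total]."""
    total = int(np.asarray(site.counts).sum())
    return total < min_total or total > max_total


def error_rate_filter(est: SiteEstimate, max_eps: float = 0.01) -> bool:
    """Flag iff the error-rate estimate strictly exceeds ``max_eps``."""
    return est.eps_hat > max_eps


def apply_filters(
    sites: Sequence[SiteCounts],
    estimates: Iterable[SiteEstimate | None],
    mask: RegionMask | None = None,
    config: FilterConfig | None = None,
) -> list[FilterVerdict]:
    """Evaluate all four filters on each site, accumulating every flag."""
    config = config or FilterConfig()
    verdicts = []
    for site, est in zip(sites, estimates):
        flags = set()
        if est is not None and detect_multiallelic(
            site,
            est,
            config.multiallelic_min_reads,
            config.multiallelic_alpha,
        ):
            flags.add(MULTIALLELIC)
        if coverage_filter(
            site, config.min_total_coverage, config.max_total_coverage
        ):
            flags.add(COVERAGE)
        if est is not None and error_rate_filter(est, config.max_error_rate):
            flags.add(ERROR_RATE)
        if mask is not None and mask.is_masked(site.scaffold, site.position):
            flags.add(REPEAT)
        verdicts.append(
            FilterVerdict(site.scaffold, site.position, frozenset(flags))
        )
    return verdicts


def apply_filters_batch(
    counts: np.ndarray,
    scaffolds: np.ndarray,
    positions: np.ndarray,
    est: BatchEstimates,
    mask: RegionMask | None,
    config: FilterConfig,
) -> tuple[np.ndarray, list[frozenset[str]]]:
    """Vectorised :func:`apply_filters` over a ``(S, L, 4)`` count array.

    Returns a boolean pass vector and per-site flag sets.
    """
    S = counts.shape[0]
    depth_line = counts.sum(axis=2)
    eligible = depth_line >= config.multiallelic_min_reads
    pooled_elig = (counts * eligible[:, :, None]).sum(axis=1)
    multi = np.zeros(S, dtype=bool)
    any_elig = eligible.any(axis=1)
    if any_elig.any():
        multi[any_elig] = _multiallelic_from_pooled(
            pooled_elig[any_elig],
            est.eps[any_elig],
            config.multiallelic_min_reads,
            config.multiallelic_alpha,
        )
    total = depth_line.sum(axis=1)
    cov = (total < config.min_total_coverage) | (total > config.max_total_coverage)
    err = est.eps > config.max_error_rate
    rep = np.zeros(S, dtype=bool)
    if mask is not None:
        for scaf in np.unique(scaffolds.astype(str)):
            sel = scaffolds.astype(str) == scaf
            rep[sel] = mask.mask_positions(scaf, positions[sel])
    passed = ~(multi | cov | err | rep)
    empty: frozenset[str] = frozenset()
    flags: list[frozenset[str]] = [empty] * S
    for i in np.nonzero(~passed)[0]:
        f = set()
        if multi[i]:
            f.add(MULTIALLELIC)
        if cov[i]:
            f.add(COVERAGE)
        if err[i]:
            f.add(ERROR_RATE)
        if rep[i]:
            f.add(REPEAT)
        flags[i] = frozenset(f)
    return passed, flags
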