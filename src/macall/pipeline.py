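"""End-to-end orchestration of a single time point's calling run.

Runs the whole chain — allele picking, per-site EM, posterior genotype
calls, exact binomial filtering, problematic-site filters, callability
and candidate identification — over a :class:`~macall.io_formats.SiteTable`
with vectorised kernels.  The scalar operations in ``site_model``,
``genotype_caller``, ``site_filters`` and ``mutation_finder`` define the
semantics; this module reproduces them in bulk, delegating every
non-trivial exact-test evaluation to the same
:func:`~macall.genotype_caller.small_p_pvalue` routine.

The only shortcut taken is analytic, not approximate: when a line has
no reads of the alternative allele (n_a = 0) and the observed outcome
is provably the modal outcome of the homozygous null — which holds iff
P(success) >= n * P(failure), i.e. (1 - eps/3) >= n * eps/3 — every
outcome qualifies for the small-p sum, so the p-value is exactly 1 and
the ancestral call stands without enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotype_caller import small_p_pvalue, _hom_probs
from .io_formats import NUCLEOTIDES, RegionMask, SiteTable
from .mutation_finder import (
    ANC_NOT_HOMREF,
    ANC_TIE,
    FILTERED,
    LOW_DEPTH,
    MISSING_CALL,
    OK,
    CandidateMutation,
)
from .site_filters import FilterConfig, apply_filters_batch
from .site_model import BatchEstimates, estimate_sites

NO_CALL_CODE = -1


@dataclass
class RunConfig:
    """All pipeline tunables, defaulting to the published settings.

    min_reads: minimum reads to call a line's genotype (8; 6 is the
    sensitivity setting).  alpha_het / alpha_hom: significance levels of
    the exact binomial test under heterozygous / homozygous nulls
    (0.025 / 0.05; the heterozygous level is halved because chance
    deviations from a 50:50 read split are more likely).  max_error_rate:
    sites with a larger error-rate estimate are removed (0.01).
    Coverage bounds apply to the pooled depth over lines.  snp_alpha:
    significance level of the polymorphism LRT below which a site is
    treated as bi-allelic downstream (0.05).  hom_model selects the
    homozygous-null success probability: "conditional" (1 - eps/3) or
    "complement" (1 - eps).
    """

    min_reads: int = 8
    alpha_het: float = 0.025
    alpha_hom: float = 0.05
    max_error_rate: float = 0.01
    min_total_coverage: int = 40
    max_total_coverage: int = 400
    multiallelic_min_reads: int = 6
    multiallelic_alpha: float = 0.05
    snp_alpha: float = 0.05
    hom_model: str = "conditional"
    seed: int = 0

    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            min_total_coverage=self.min_total_coverage,
            max_total_coverage=self.max_total_coverage,
            max_error_rate=self.max_error_rate,
            multiallelic_alpha=self.multiallelic_alpha,
            multiallelic_min_reads=self.multiallelic_min_reads,
        )


_REASON_NAMES = {
    0: OK,
    1: FILTERED,
    2: ANC_TIE,
    3: LOW_DEPTH,
    4: MISSING_CALL,
    5: ANC_NOT_HOMREF,
}


@dataclass
class TimePointResult:
    """All per-site artifacts of one time point's run."""

    table: SiteTable
    time_point: int
    est: BatchEstimates
    bgc_codes: np.ndarray  # (S, L): 0 MM, 1 Mm, 2 mm, -1 no-call
    anc_codes: np.ndarray  # (S,): 0 hom-major, 1 het, 2 hom-minor, -1 none
    call_codes: np.ndarray  # (S, L) filtered calls, -1 no-call
    p_anc: np.ndarray  # (S, L), NaN where untested
    p_het: np.ndarray
    passed: np.ndarray  # (S,) site filters
    filter_flags: list[frozenset[str]]
    reason_codes: np.ndarray  # (S,) callability reason
    candidates: list[CandidateMutation] = field(default_factory=list)

    @property
    def callable_sites(self) -> np.ndarray:
        return self.reason_codes == 0

    @property
    def n_callable(self) -> int:
        return int(self.callable_sites.sum())

    def callable_keys(self) -> set[tuple[str, int]]:
        idx = np.nonzero(self.callable_sites)[0]
        return {
            (str(self.table.scaffolds[i]), int(self.table.positions[i]))
            for i in idx
        }

    def called_keys(self) -> set[tuple[str, int, str]]:
        """(scaffold, position, line) keys with a filtered genotype call."""
        out = set()
        sites, lines = np.nonzero(self.call_codes >= 0)
        for s, l in zip(sites, lines):
            out.add(
                (
                    str(self.table.scaffolds[s]),
                    int(self.table.positions[s]),
                    self.table.line_ids[l],
                )
            )
        return out

    def callable_by_ref_nt(self) -> dict[str, int]:
        """Callable-site counts per reference nucleotide (spectrum N_X)."""
        out: dict[str, int] = {}
        refs = self.table.ref_codes[self.callable_sites]
        for code in range(4):
            out[NUCLEOTIDES[code]] = int((refs == code).sum())
        return out

    def reasons(self) -> list[str]:
        return [_REASON_NAMES[int(c)] for c in self.reason_codes]

    def candidates_frame(self) -> pd.DataFrame:
        rows = [
            {
                "scaffold": c.scaffold,
                "position": c.position,
                "line": c.line_id,
                "time_point": c.time_point,
                "ancestral_nt": c.ancestral_nt,
                "mutant_nt": c.mutant_nt,
                "genotype": "".join(c.called_genotype),
            }
            for c in self.candidates
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "scaffold",
                "position",
                "line",
                "time_point",
                "ancestral_nt",
                "mutant_nt",
                "genotype",
            ],
        )

    def estimates_frame(self) -> pd.DataFrame:
        e = self.est
        minor = np.where(
            e.minor >= 0,
            np.array(list(NUCLEOTIDES))[np.clip(e.minor, 0, 3)],
            "-",
        )
        return pd.DataFrame(
            {
                "scaffold": self.table.scaffolds,
                "position": self.table.positions,
                "major": np.array(list(NUCLEOTIDES))[np.clip(e.major, 0, 3)],
                "minor": minor,
                "eps_hat": e.eps,
                "P_MM": e.geno_freqs[:, 0],
                "P_Mm": e.geno_freqs[:, 1],
                "P_mm": e.geno_freqs[:, 2],
                "lrt_stat": e.lrt,
                "polymorphic_p": e.polymorphic_p,
            }
        )

    def calls_frame(self) -> pd.DataFrame:
        """Long-format per-site per-line filtered call table."""
        S, L = self.call_codes.shape
        geno_strings = _genotype_strings(self.est)
        records = []
        for s in range(S):
            for l in range(L):
                code = self.call_codes[s, l]
                records.append(
                    {
                        "scaffold": self.table.scaffolds[s],
                        "position": int(self.table.positions[s]),
                        "line": self.table.line_ids[l],
                        "genotype": geno_strings[s][code] if code >= 0 else "./.",
                        "depth": int(self.table.counts[s, l].sum()),
                        "p_anc": self.p_anc[s, l],
                        "p_het": self.p_het[s, l],
                    }
                )
        return pd.DataFrame(records)


def _genotype_strings(est: BatchEstimates) -> list[tuple[str, str, str]]:
    out = []
    for i in range(len(est.major)):
        M = NUCLEOTIDES[est.major[i]]
        m = NUCLEOTIDES[est.minor[i]] if est.minor[i] >= 0 else M
        out.append((M + M, "".join(sorted(M + m)), m + m))
    return out


def _bgc_codes_batch(
    counts: np.ndarray, est: BatchEstimates, min_reads: int
) -> np.ndarray:
    """Vectorised posterior genotype calls (argmax codes) for all lines."""
    S, L, _ = counts.shape
    take = lambda idx: np.take_along_axis(
        counts, np.clip(idx, 0, 3)[:, None, None], axis=2
    )[:, :, 0].astype(float)
    n_M = take(est.major)
    has_minor = est.minor >= 0
    n_m = np.where(has_minor[:, None], take(est.minor), 0.0)
    depth = counts.sum(axis=2)
    n_o = depth - n_M - n_m
    eps = est.eps[:, None]

    with np.errstate(divide="ignore"):
        log_err = np.log(eps / 3.0)
        log_hom = np.log1p(-eps)
        log_het = np.log(0.5 - eps / 3.0)
        log_prior = np.log(est.geno_freqs)  # (S, 3)
    # monomorphic sites: degenerate prior on MM
    log_prior = np.where(
        has_minor[:, None], log_prior, np.array([0.0, -np.inf, -np.inf])
    )

    def xlogy(x, logy):
        with np.errstate(invalid="ignore"):
            return np.where(x > 0, x * logy, 0.0)

    ll = np.stack(
        [
            xlogy(n_M, log_hom) + xlogy(n_m + n_o, log_err),
            xlogy(n_M + n_m, log_het) + xlogy(n_o, log_err),
            xlogy(n_m, log_hom) + xlogy(n_M + n_o, log_err),
        ],
        axis=2,
    )
    with np.errstate(invalid="ignore"):
        post = ll + log_prior[:, None, :]
    post = np.where(np.isnan(post), -np.inf, post)
    codes = np.argmax(post, axis=2).astype(np.int8)
    codes[depth < min_reads] = NO_CALL_CODE
    codes[~np.isfinite(post).any(axis=2)] = NO_CALL_CODE
    return codes


def _consensus_codes(bgc_codes: np.ndarray) -> np.ndarray:
    """Most frequent non-missing genotype code per site; ties -> -1."""
    S = bgc_codes.shape[0]
    tallies = np.stack(
        [(bgc_codes == g).sum(axis=1) for g in (0, 1, 2)], axis=1
    )
    order = np.sort(tallies, axis=1)
    top, second = order[:, 2], order[:, 1]
    anc = np.argmax(tallies, axis=1).astype(np.int8)
    anc[(top == 0) | (top == second)] = -1
    return anc


def run_time_point(
    table: SiteTable,
    mask: RegionMask | None = None,
    config: RunConfig | None = None,
    time_point: int = 1,
) -> TimePointResult:
    """Run estimation, calling, filtering and mutation identification."""
    config = config or RunConfig()
    counts = table.counts
    S, L, _ = counts.shape

    est = estimate_sites(counts)

    # SNP gate: bi-allelic structure is honoured only at significantly
    # polymorphic sites; elsewhere the site is processed as monomorphic,
    # which keeps isolated error reads from being analysed as alleles
    with np.errstate(invalid="ignore"):
        snp = est.polymorphic_p < config.snp_alpha
    gated = replace(est, minor=np.where(snp, est.minor, -1))

    bgc = _bgc_codes_batch(counts, gated, config.min_reads)
    anc = _consensus_codes(bgc)
    anc[~est.valid] = -1

    call_codes, p_anc, p_het = _filter_calls_batch(counts, gated, anc, config)

    passed, flags = apply_filters_batch(
        counts,
        table.scaffolds,
        table.positions,
        est,
        mask,
        config.filter_config(),
    )

    reason = _callability_batch(
        table, gated, anc, call_codes, passed, config.min_reads
    )
    candidates = _candidates_batch(
        table, gated, anc, call_codes, reason, time_point
    )
    return TimePointResult(
        table=table,
        time_point=time_point,
        est=est,
        bgc_codes=bgc,
        anc_codes=anc,
        call_codes=call_codes,
        p_anc=p_anc,
        p_het=p_het,
        passed=passed,
        filter_flags=flags,
        reason_codes=reason,
        candidates=candidates,
    )


def _filter_calls_batch(
    counts: np.ndarray,
    est: BatchEstimates,
    anc: np.ndarray,
    config: RunConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised exact-binomial filtered calls for every (site, line)."""
    S, L, _ = counts.shape
    take = lambda idx: np.take_along_axis(
        counts, np.clip(idx, 0, 3)[:, None, None], axis=2
    )[:, :, 0]
    n_Maj = take(est.major)
    has_minor = est.minor >= 0
    n_min = np.where(has_minor[:, None], take(est.minor), 0)
    depth = counts.sum(axis=2)

    call = np.full((S, L), NO_CALL_CODE, dtype=np.int8)
    p_anc = np.full((S, L), np.nan)
    p_het = np.full((S, L), np.nan)

    enough = depth >= config.min_reads
    anc_hom0 = (anc == 0)[:, None] & enough  # ancestor = major homozygote
    anc_hom2 = (anc == 2)[:, None] & enough  # ancestor = minor homozygote
    anc_is_het = (anc == 1)[:, None] & enough

    # allele counts relative to the ancestral allele
    n_A = np.where(anc_hom2, n_min, n_Maj)
    n_a = np.where(anc_hom2, n_Maj, n_min)
    n_pair = n_A + n_a

    _hom_probs(0.0, config.hom_model)  # validate the model name early
    a_vec = (
        1.0 - est.eps / 3.0 if config.hom_model == "conditional" else 1.0 - est.eps
    )
    b_vec = est.eps / 3.0

    hom_any = anc_hom0 | anc_hom2
    # fast path: no alternative reads and observed outcome provably modal
    modal = a_vec[:, None] >= n_pair * b_vec[:, None]
    fast = hom_any & (n_a == 0) & modal & (n_pair > 0)
    call[fast] = np.broadcast_to(anc[:, None], (S, L))[fast]
    p_anc[fast] = 1.0

    # exact enumeration for everything else under a homozygous ancestor
    slow = hom_any & ~fast
    anc_b = np.broadcast_to(anc[:, None], (S, L))
    minor_b = np.broadcast_to(has_minor[:, None], (S, L))
    for s, l in zip(*np.nonzero(slow)):
        if n_pair[s, l] == 0:
            continue
        eps = float(est.eps[s])
        pa = small_p_pvalue(
            int(n_A[s, l]), int(n_a[s, l]), "hom", eps, config.hom_model
        )
        p_anc[s, l] = pa
        if pa >= config.alpha_hom:
            call[s, l] = anc_b[s, l]
            continue
        if not minor_b[s, l]:
            continue
        ph = small_p_pvalue(
            int(n_A[s, l]), int(n_a[s, l]), "het", eps, config.hom_model
        )
        p_het[s, l] = ph
        if ph >= config.alpha_het and n_A[s, l] >= 2 and n_a[s, l] >= 2:
            call[s, l] = 1

    # heterozygous ancestor
    for s, l in zip(*np.nonzero(anc_is_het)):
        if n_pair[s, l] == 0:
            continue
        eps = float(est.eps[s])
        ph = small_p_pvalue(int(n_A[s, l]), int(n_a[s, l]), "het", eps)
        p_anc[s, l] = ph
        p_het[s, l] = ph
        if ph >= config.alpha_het:
            call[s, l] = 1
        else:
            row = counts[s, l]
            nz = np.nonzero(row)[0]
            if len(nz) == 1:  # all reads one nucleotide -> homozygote
                if nz[0] == est.major[s]:
                    call[s, l] = 0
                elif est.minor[s] >= 0 and nz[0] == est.minor[s]:
                    call[s, l] = 2
    return call, p_anc, p_het


def _callability_batch(
    table: SiteTable,
    est: BatchEstimates,
    anc: np.ndarray,
    call_codes: np.ndarray,
    passed: np.ndarray,
    min_reads: int,
) -> np.ndarray:
    S, L = call_codes.shape
    depth = table.counts.sum(axis=2)
    reason = np.zeros(S, dtype=np.int8)
    uncalled = call_codes < 0
    any_uncalled = uncalled.any(axis=1)
    low_depth_first = np.zeros(S, dtype=bool)
    if any_uncalled.any():
        # reason reflects the first uncalled line, as in the scalar path
        first = np.argmax(uncalled, axis=1)
        low_depth_first = depth[np.arange(S), first] < min_reads

    anc_allele = np.where(anc == 2, est.minor, est.major)
    hom_ref = ((anc == 0) | (anc == 2)) & (anc_allele == table.ref_codes)

    reason[~hom_ref] = 5  # ANC_NOT_HOMREF
    reason[any_uncalled & low_depth_first] = 3
    reason[any_uncalled & ~low_depth_first] = 4
    reason[anc < 0] = 2
    reason[~passed] = 1
    return reason


def _candidates_batch(
    table: SiteTable,
    est: BatchEstimates,
    anc: np.ndarray,
    call_codes: np.ndarray,
    reason: np.ndarray,
    time_point: int,
) -> list[CandidateMutation]:
    callable_sites = reason == 0
    if not callable_sites.any():
        return []
    # mutant = called genotype contains an allele missing from the ancestor
    anc_b = anc[:, None]
    is_mutant = (call_codes >= 0) & (call_codes != anc_b) & callable_sites[:, None]
    n_mutant = is_mutant.sum(axis=1)
    exclusive = callable_sites & (n_mutant == 1)
    out: list[CandidateMutation] = []
    geno_strings = None
    for s in np.nonzero(exclusive)[0]:
        l = int(np.argmax(is_mutant[s]))
        anc_nt = NUCLEOTIDES[est.major[s] if anc[s] == 0 else est.minor[s]]
        mut_nt = NUCLEOTIDES[est.minor[s] if anc[s] == 0 else est.major[s]]
        code = call_codes[s, l]
        M = NUCLEOTIDES[est.major[s]]
        m = NUCLEOTIDES[est.minor[s]] if est.minor[s] >= 0 else M
        genos = ((M, M), tuple(sorted((M, m))), (m, m))
        out.append(
            CandidateMutation(
                str(table.scaffolds[s]),
                int(table.positions[s]),
                table.line_ids[l],
                anc_nt,
                mut_nt,
                time_point,
                genos[code],
            )
        )
    return out
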