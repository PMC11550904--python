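"""Ancestral-genotype inference, site callability and mutation identification.

The ancestral genotype at a site is the consensus (most abundant)
genotype among the lines' unfiltered posterior calls; MA lines descend
from a single progenitor, so absent mutation they share its genotype.
A site is *callable* when it passed all filters, every line has a
filtered genotype called from at least the minimum read count, and the
ancestral genotype is homozygous for the reference nucleotide (the
latter guards against reference bias).  At callable sites, a mutant
nucleotide is one present in a line's called genotype but absent from
the ancestral genotype; candidates are kept only when exactly one line
carries a mutant nucleotide at the site.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .genotype_caller import GenotypeCall
from .site_filters import FilterVerdict

OK = "OK"
FILTERED = "FILTERED"
MISSING_CALL = "MISSING_CALL"
LOW_DEPTH = "LOW_DEPTH"
ANC_NOT_HOMREF = "ANC_NOT_HOMREF"
ANC_TIE = "ANC_TIE"


@dataclass(frozen=True)
class CandidateMutation:
    scaffold: str
    position: int
    line_id: str
    ancestral_nt: str
    mutant_nt: str
    time_point: int
    called_genotype: tuple[str, str]

    def __post_init__(self) -> None:
        if self.mutant_nt == self.ancestral_nt:
            raise ValueError("mutant nucleotide equals ancestral nucleotide")

    @property
    def site_key(self) -> tuple[str, int]:
        return (self.scaffold, self.position)


@dataclass(frozen=True)
class CallabilityRecord:
    scaffold: str
    position: int
    reason: str

    @property
    def callable(self) -> bool:
        return self.reason == OK

    @property
    def site_key(self) -> tuple[str, int]:
        return (self.scaffold, self.position)


def infer_ancestral(
    calls: Sequence[GenotypeCall],
) -> tuple[str, str] | None:
    """Consensus genotype over the lines' calls; ties void the site."""
    tally = Counter(
        tuple(sorted(c.genotype)) for c in calls if c.genotype is not None
    )
    if not tally:
        return None
    ranked = tally.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return None
    return ranked[0][0]


def assess_callability(
    scaffold: str,
    position: int,
    ref_nt: str,
    verdict: FilterVerdict,
    filtered_calls: Sequence[GenotypeCall],
    ancestral: tuple[str, str] | None,
    min_reads: int = 8,
) -> CallabilityRecord:
    """Classify a site as callable or give the first disqualifying reason."""
    if not verdict.passed:
        return CallabilityRecord(scaffold, position, FILTERED)
    if ancestral is None:
        return CallabilityRecord(scaffold, position, ANC_TIE)
    for call in filtered_calls:
        if call.genotype is None:
            reason = LOW_DEPTH if call.depth < min_reads else MISSING_CALL
            return CallabilityRecord(scaffold, position, reason)
        if call.depth < min_reads:
            return CallabilityRecord(scaffold, position, LOW_DEPTH)
    if ancestral[0] != ancestral[1] or ancestral[0] != ref_nt:
        return CallabilityRecord(scaffold, position, ANC_NOT_HOMREF)
    return CallabilityRecord(scaffold, position, OK)


def identify_mutations(
    sites: Iterable[tuple[str, int, str]],
    filtered_calls: Iterable[Sequence[GenotypeCall]],
    callability: Iterable[CallabilityRecord],
    ancestral: Iterable[tuple[str, str] | None],
    time_point: int = 1,
) -> list[CandidateMutation]:
    """Emit exclusive single-line candidate mutations at callable sites.

    ``sites`` yields (scaffold, position, ref_nt) triples aligned with
    the per-site call lists, callability records and ancestral
    genotypes.
    """
    out: list[CandidateMutation] = []
    for (scaffold, position, _ref), calls, rec, anc in zip(
        sites, filtered_calls, callability, ancestral
    ):
        if not rec.callable or anc is None:
            continue
        anc_set = set(anc)
        hits: list[CandidateMutation] = []
        mutant_lines = 0
        for call in calls:
            if call.genotype is None:
                continue
            novel = [nt for nt in set(call.genotype) if nt not in anc_set]
            if not novel:
                continue
            mutant_lines += 1
            for nt in sorted(novel):
                hits.append(
                    CandidateMutation(
                        scaffold,
                        position,
                        call.line_id,
                        anc[0],
                        nt,
                        time_point,
                        call.genotype,
                    )
                )
        if mutant_lines == 1:  # exclusivity: one line only, else drop site
            out.extend(hits)
    return out
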