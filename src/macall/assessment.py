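"""Time-series assessment of candidate mutations.

True mutations persist within an MA line across sequencing time points
but are never shared between independently evolving lines.  Cross-line
sharing of candidates therefore proxies the false discovery rate, and
within-line sharing the positive predictive value.  Two candidates
match when they hit the same site with the same mutant nucleotide: two
different alleles at one position are distinct mutation events.

All rates with a zero denominator are reported as NaN ("no evidence"),
never as 0 ("no sharing").
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .mutation_finder import CandidateMutation

SAME_LINE = "same_line_match"
CROSS_LINE = "cross_line_match"
NONE = "none"


@dataclass(frozen=True)
class SharingSummary:
    pair: tuple[int, int]
    n_candidates_callable_later: int
    n_within: int
    n_cross: int

    @property
    def within_rate(self) -> float:
        if self.n_candidates_callable_later == 0:
            return math.nan
        return self.n_within / self.n_candidates_callable_later

    @property
    def cross_rate(self) -> float:
        if self.n_candidates_callable_later == 0:
            return math.nan
        return self.n_cross / self.n_candidates_callable_later


def match_candidates(a: CandidateMutation, b: CandidateMutation) -> str:
    """Classify a candidate pair: same-line match, cross-line match, none."""
    if a.site_key != b.site_key or a.mutant_nt != b.mutant_nt:
        return NONE
    return SAME_LINE if a.line_id == b.line_id else CROSS_LINE


def sharing_rates(
    cands_by_tp: Mapping[int, Sequence[CandidateMutation]],
    callable_by_tp: Mapping[int, set[tuple[str, int]]],
    pair: tuple[int, int],
) -> SharingSummary:
    """Within- and cross-line sharing for an (earlier, later) pair.

    The denominator is the number of candidates at the earlier time
    point whose site is callable at the later one.
    """
    earlier_tp, later_tp = pair
    later_callable = callable_by_tp[later_tp]
    later = cands_by_tp[later_tp]
    later_keys = {(c.site_key, c.mutant_nt, c.line_id) for c in later}
    later_sites = {}
    for c in later:
        later_sites.setdefault((c.site_key, c.mutant_nt), set()).add(c.line_id)
    n_denom = n_within = n_cross = 0
    for c in cands_by_tp[earlier_tp]:
        if c.site_key not in later_callable:
            continue
        n_denom += 1
        if (c.site_key, c.mutant_nt, c.line_id) in later_keys:
            n_within += 1
        other = later_sites.get((c.site_key, c.mutant_nt), set()) - {c.line_id}
        if other:
            n_cross += 1
    return SharingSummary(pair, n_denom, n_within, n_cross)


def unconfirmed_rate(
    cands_by_tp: Mapping[int, Sequence[CandidateMutation]],
    calls_by_tp: Mapping[int, set[tuple[str, int, str]]],
    first_tp: int,
    later_tp: int,
) -> float:
    """Fraction of candidates first seen at ``first_tp`` not re-found later.

    Conditioning: only candidates whose line has a genotype call at the
    site at both time points enter the denominator.  ``calls_by_tp``
    holds (scaffold, position, line_id) keys with a non-missing call.
    A candidate counts as "first identified" at ``first_tp`` when no
    earlier time point has a same-line match for it.
    """
    earlier_tps = [t for t in cands_by_tp if t < first_tp]
    prior = {
        (c.site_key, c.mutant_nt, c.line_id)
        for t in earlier_tps
        for c in cands_by_tp[t]
    }
    later_keys = {
        (c.site_key, c.mutant_nt, c.line_id) for c in cands_by_tp[later_tp]
    }
    later_calls = calls_by_tp[later_tp]
    n = unconfirmed = 0
    for c in cands_by_tp[first_tp]:
        key = (c.site_key, c.mutant_nt, c.line_id)
        if key in prior:
            continue
        if (c.scaffold, c.position, c.line_id) not in later_calls:
            continue
        n += 1
        if key not in later_keys:
            unconfirmed += 1
    return math.nan if n == 0 else unconfirmed / n


def sharing_matrix(
    cands_by_tp: Mapping[int, Sequence[CandidateMutation]],
) -> pd.DataFrame:
    """Counts of shared candidates between (line, time point) cells.

    Symmetric matrix indexed by (line, tp); the diagonal blocks (same
    line, different time points) hold within-line sharing counts.  Cells
    on the exact diagonal (same line and time point) are zero.
    """
    cells = sorted(
        {(c.line_id, tp) for tp, cs in cands_by_tp.items() for c in cs}
    )
    index = pd.MultiIndex.from_tuples(cells, names=["line", "tp"])
    mat = pd.DataFrame(0, index=index, columns=index)
    flat = [
        (tp, c) for tp, cs in sorted(cands_by_tp.items()) for c in cs
    ]
    for i, (tp_i, a) in enumerate(flat):
        for tp_j, b in flat[i + 1 :]:
            if (tp_i, a.line_id) == (tp_j, b.line_id):
                continue
            if a.site_key == b.site_key and a.mutant_nt == b.mutant_nt:
                ia, ib = (a.line_id, tp_i), (b.line_id, tp_j)
                mat.at[ia, ib] += 1
                mat.at[ib, ia] += 1
    return mat
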