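"""Readers and writers for the pipeline's external formats.

Three text formats are handled:

* samtools-style multi-sample ``mpileup`` records (one line per site:
  chrom, 1-based position, reference base, then a depth/bases/quals
  triple per sample),
* the *pro* nucleotide-read-count format: per site, per line, the counts
  of A, C, G and T joined by slashes (``nA/nC/nG/nT``).  This is the
  pipeline's core exchange format,
* BED3 interval files used as repeat masks (0-based, half-open).

mpileup and pro coordinates are 1-based; BED is 0-based half-open.
Strand is not tracked: counts are pooled across strands, as in the
slash-count representation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

NUCLEOTIDES = "ACGT"
NUC_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}

#: integer code used for an undetermined reference base
N_CODE = -1


class ParseError(ValueError):
    """Raised for malformed input records, with file coordinates."""


@dataclass(frozen=True)
class SiteCounts:
    """Per-site, per-line A/C/G/T read counts plus the reference base.

    ``counts`` is an ordered tuple over MA lines of ``(n_A, n_C, n_G,
    n_T)`` tuples.
    """

    scaffold: str
    position: int  # 1-based
    ref_nt: str  # one of A, C, G, T, N
    counts: tuple[tuple[int, int, int, int], ...]

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_nt not in "ACGTN":
            raise ValueError(f"invalid reference nucleotide {self.ref_nt!r}")
        for line_counts in self.counts:
            if len(line_counts) != 4 or any(c < 0 for c in line_counts):
                raise ValueError(f"invalid counts {line_counts!r}")

    @property
    def n_lines(self) -> int:
        return len(self.counts)

    def pooled(self) -> tuple[int, int, int, int]:
        """Counts summed over lines."""
        return tuple(int(sum(c[k] for c in self.counts)) for k in range(4))


@dataclass
class SiteTable:
    """Column-oriented batch of sites for vectorised processing.

    Equivalent to a sequence of :class:`SiteCounts` sharing one set of
    line identifiers; ``counts`` has shape ``(n_sites, n_lines, 4)``.
    """

    scaffolds: np.ndarray  # object dtype, shape (S,)
    positions: np.ndarray  # int64, 1-based, shape (S,)
    ref_codes: np.ndarray  # int8, A/C/G/T -> 0..3, N -> -1, shape (S,)
    counts: np.ndarray  # int64, shape (S, L, 4)
    line_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.line_ids:
            self.line_ids = tuple(
                f"L{i + 1:02d}" for i in range(self.counts.shape[1])
            )

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    @property
    def n_lines(self) -> int:
        return self.counts.shape[1]

    @classmethod
    def from_sites(
        cls, sites: Sequence[SiteCounts], line_ids: Sequence[str] = ()
    ) -> "SiteTable":
        scaffolds = np.array([s.scaffold for s in sites], dtype=object)
        positions = np.array([s.position for s in sites], dtype=np.int64)
        refs = np.array(
            [NUC_INDEX.get(s.ref_nt, N_CODE) for s in sites], dtype=np.int8
        )
        counts = np.array([s.counts for s in sites], dtype=np.int64)
        return cls(scaffolds, positions, refs, counts, tuple(line_ids))

    def to_sites(self) -> list[SiteCounts]:
        out = []
        for i in range(self.n_sites):
            ref = "N" if self.ref_codes[i] < 0 else NUCLEOTIDES[self.ref_codes[i]]
            out.append(
                SiteCounts(
                    str(self.scaffolds[i]),
                    int(self.positions[i]),
                    ref,
                    tuple(tuple(int(x) for x in row) for row in self.counts[i]),
                )
            )
        return out


# ---------------------------------------------------------------------------
# mpileup
# ---------------------------------------------------------------------------

_IGNORED_BASES = set("*Nn><")


def _parse_base_string(
    bases: str, ref_code: int, where: str
) -> tuple[int, int, int, int]:
    """Tally one sample's mpileup base string into A/C/G/T counts.

    ``.``/``,`` count toward the reference base; ``^`` consumes the
    following mapping-quality character; ``$`` is ignored; ``+k``/``-k``
    indel codes consume the k inserted/deleted bases; ``*``, ``N`` and
    reference skips carry no nucleotide evidence and are ignored.
    """
    counts = [0, 0, 0, 0]
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            if i + 1 >= n:
                raise ParseError(f"{where}: dangling '^' in base string")
            i += 2
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise ParseError(f"{where}: indel code without length")
            k = int(bases[i + 1 : j])
            if j + k > n:
                raise ParseError(f"{where}: indel length overruns base string")
            i = j + k
            continue
        if c in ".,":
            if ref_code >= 0:
                counts[ref_code] += 1
            i += 1
            continue
        upper = c.upper()
        if upper in NUC_INDEX:
            counts[NUC_INDEX[upper]] += 1
            i += 1
            continue
        if c in _IGNORED_BASES:
            i += 1
            continue
        raise ParseError(f"{where}: unrecognised symbol {c!r} in base string")
    return tuple(counts)


def parse_mpileup_record(line_text: str, n_lines: int) -> SiteCounts:
    """Parse one multi-sample mpileup line into per-line base counts.

    The record must have ``3 + 3 * n_lines`` fields: chrom, pos, ref,
    then (depth, bases, quals) per line.  A sample with zero depth may
    be encoded as ``0 * *``.
    """
    fields = line_text.rstrip("\n").split("\t")
    if len(fields) == 1:
        fields = line_text.split()
    expected = 3 + 3 * n_lines
    if len(fields) != expected:
        raise ParseError(
            f"mpileup record has {len(fields)} fields, expected {expected}"
        )
    scaffold, pos_s, ref = fields[0], fields[1], fields[2].upper()
    try:
        position = int(pos_s)
    except ValueError as exc:
        raise ParseError(f"{scaffold}: non-integer position {pos_s!r}") from exc
    if ref not in "ACGTN":
        raise ParseError(f"{scaffold}:{position}: reference base {ref!r}")
    where = f"{scaffold}:{position}"
    ref_code = NUC_INDEX.get(ref, N_CODE)
    counts = []
    for k in range(n_lines):
        bases = fields[4 + 3 * k]
        counts.append(_parse_base_string(bases, ref_code, where))
    return SiteCounts(scaffold, position, ref, tuple(counts))


def read_mpileup(stream: Iterable[str], n_lines: int) -> Iterator[SiteCounts]:
    for line in stream:
        if not line.strip():
            continue
        yield parse_mpileup_record(line, n_lines)


# ---------------------------------------------------------------------------
# pro format
# ---------------------------------------------------------------------------

PRO_HEADER_PREFIX = "#scaffold\tposition\tref"


def read_pro(stream: Iterable[str]) -> Iterator[SiteCounts]:
    """Stream :class:`SiteCounts` from a pro file.

    The header row declares the line identifiers; body rows are
    ``scaffold  position  ref  nA/nC/nG/nT ...`` tab-separated.
    """
    it = iter(stream)
    try:
        header = next(it)
    except StopIteration:
        return
    if not header.startswith("#"):
        raise ParseError("pro file must start with a '#' header row")
    n_lines = len(header.rstrip("\n").split("\t")) - 3
    if n_lines < 1:
        raise ParseError("pro header declares no line identifiers")
    for row_no, line in enumerate(it, start=2):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 3 + n_lines:
            raise ParseError(
                f"row {row_no}: {len(fields)} fields, expected {3 + n_lines}"
            )
        try:
            position = int(fields[1])
        except ValueError as exc:
            raise ParseError(f"row {row_no}: non-integer position") from exc
        if position <= 0:
            raise ParseError(f"row {row_no}: position must be positive")
        counts = []
        for f in fields[3:]:
            parts = f.split("/")
            if len(parts) != 4:
                raise ParseError(f"row {row_no}: count field {f!r}")
            try:
                counts.append(tuple(int(p) for p in parts))
            except ValueError as exc:
                raise ParseError(f"row {row_no}: non-integer count in {f!r}") from exc
        try:
            yield SiteCounts(fields[0], position, fields[2], tuple(counts))
        except ValueError as exc:
            raise ParseError(f"row {row_no}: {exc}") from exc


def pro_line_ids(stream: Iterable[str]) -> tuple[str, ...]:
    """Line identifiers declared in a pro file header."""
    it = iter(stream)
    header = next(it)
    if not header.startswith("#"):
        raise ParseError("pro file must start with a '#' header row")
    return tuple(header.rstrip("\n").split("\t")[3:])


def write_pro(
    sites: Iterable[SiteCounts],
    stream: io.TextIOBase,
    line_ids: Sequence[str] = (),
) -> None:
    line_ids = list(line_ids)
    first = True
    for site in sites:
        if first:
            if not line_ids:
                line_ids = [f"L{i + 1:02d}" for i in range(site.n_lines)]
            stream.write(PRO_HEADER_PREFIX + "\t" + "\t".join(line_ids) + "\n")
            first = False
        row = [site.scaffold, str(site.position), site.ref_nt]
        row.extend("/".join(str(c) for c in lc) for lc in site.counts)
        stream.write("\t".join(row) + "\n")
    if first and line_ids:
        stream.write(PRO_HEADER_PREFIX + "\t" + "\t".join(line_ids) + "\n")


def load_pro(path) -> SiteTable:
    """Read a whole pro file into a :class:`SiteTable`."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ParseError("pro file must start with a '#' header row")
        line_ids = tuple(header.rstrip("\n").split("\t")[3:])
        sites = list(read_pro([header] + fh.readlines()))
    return SiteTable.from_sites(sites, line_ids)


def dump_pro(table: SiteTable, path) -> None:
    with open(path, "w") as fh:
        write_pro(table.to_sites(), fh, table.line_ids)


# ---------------------------------------------------------------------------
# BED repeat masks
# ---------------------------------------------------------------------------


class RegionMask:
    """Set of genomic intervals with fast point-membership queries.

    Intervals are 0-based half-open (BED convention); queries use the
    pipeline's 1-based coordinates: position p is masked iff
    ``start < p <= end`` for some interval.  Overlapping intervals are
    merged internally, so membership is idempotent.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        by_scaf: dict[str, list[tuple[int, int]]] = {}
        for scaffold, start, end in intervals:
            if start >= end:
                raise ValueError(f"empty interval [{start}, {end}) on {scaffold}")
            by_scaf.setdefault(str(scaffold), []).append((int(start), int(end)))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for scaffold, ivals in by_scaf.items():
            ivals.sort()
            merged: list[list[int]] = []
            for s, e in ivals:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[scaffold] = np.array([m[0] for m in merged])
            self._ends[scaffold] = np.array([m[1] for m in merged])

    def is_masked(self, scaffold: str, position: int) -> bool:
        """True iff the 1-based ``position`` falls in a masked interval."""
        starts = self._starts.get(scaffold)
        if starts is None:
            return False
        idx = int(np.searchsorted(starts, position - 1, side="right")) - 1
        return idx >= 0 and position - 1 < self._ends[scaffold][idx]

    def mask_positions(self, scaffold: str, positions: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`is_masked` over an array of 1-based positions."""
        starts = self._starts.get(scaffold)
        if starts is None:
            return np.zeros(len(positions), dtype=bool)
        pos0 = np.asarray(positions) - 1
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = idx >= 0
        out = np.zeros(len(pos0), dtype=bool)
        out[ok] = pos0[ok] < self._ends[scaffold][idx[ok]]
        return out


def read_bed_mask(stream: Iterable[str]) -> RegionMask:
    """Build a :class:`RegionMask` from BED3+ lines (extra columns ignored)."""
    intervals = []
    for row_no, line in enumerate(stream, start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) == 1:
            fields = line.split()
        if len(fields) < 3:
            raise ParseError(f"BED row {row_no}: fewer than 3 columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"BED row {row_no}: non-numeric coordinates") from exc
        if start >= end:
            raise ParseError(f"BED row {row_no}: start {start} >= end {end}")
        intervals.append((fields[0], start, end))
    return RegionMask(intervals)
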