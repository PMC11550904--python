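"""Count-level simulator for MA-line time-series sequencing data.

Fourteen diploid lines descend from one ancestor and evolve
independently: on each chromosome copy of each site, a mutation arises
per generation with probability ``mu_sim`` and converts the allele to a
uniformly chosen alternative nucleotide.  Mutations persist (no
reversion within a run; a second hit would overwrite, but at supported
settings its probability is negligible).  Each line is then "sequenced"
at every time point: per-site depth is Poisson with the configured mean
coverage, reads draw a chromosome copy uniformly, and each read is
mis-read to one of the three other nucleotides with probability
``error_rate`` (spread evenly) — the same per-read error model the
genotype caller assumes.

The simulator works at the nucleotide-count level: there is no read
mapping in the pipeline, so mismapping, coverage autocorrelation and
indels are deliberately out of scope.  All randomness derives from the
single configured seed via per-(time point, line) child streams, so
identical configurations give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import NUC_INDEX, NUCLEOTIDES, SiteTable


@dataclass
class SimConfig:
    n_sites: int
    mu_sim: float
    n_lines: int = 14
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    ancestral_het_fraction: float = 0.001
    generations_at_tp: tuple[int, ...] = (82, 159, 188)
    mean_coverage: tuple[float, ...] = (10.8, 13.8, 10.0)
    error_rate: float = 3e-4
    seed: int = 0
    scaffold: str = "sim1"

    def __post_init__(self) -> None:
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base composition must sum to 1")
        if any(not 0 <= p <= 1 for p in self.base_composition):
            raise ValueError("base composition probabilities must be in [0, 1]")
        gens = self.generations_at_tp
        if any(b <= a for a, b in zip(gens, gens[1:])):
            raise ValueError("generations must strictly increase across time points")
        if np.isscalar(self.mean_coverage):
            self.mean_coverage = tuple([float(self.mean_coverage)] * len(gens))
        if len(self.mean_coverage) != len(gens):
            raise ValueError("one mean coverage per time point required")

    @classmethod
    def with_composition_from_fasta(cls, fasta_path, **kwargs) -> "SimConfig":
        """Take the base composition from a reference FASTA."""
        from Bio import SeqIO

        totals = np.zeros(4)
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            seq = str(rec.seq).upper()
            for i, nt in enumerate(NUCLEOTIDES):
                totals[i] += seq.count(nt)
        if totals.sum() == 0:
            raise ValueError("no A/C/G/T bases in FASTA")
        kwargs["base_composition"] = tuple(totals / totals.sum())
        return cls(**kwargs)


@dataclass
class Truth:
    """Ground truth of a simulation: ancestry plus planted mutations.

    ``anc_genotypes`` has shape (n_sites, n_lines, 2) with nucleotide
    codes per chromosome copy (identical across lines at generation 0);
    ``events`` is the planted-mutation ledger with one row per event.
    """

    config: SimConfig
    ref_codes: np.ndarray
    anc_genotypes: np.ndarray
    events: pd.DataFrame
    line_ids: tuple[str, ...] = field(default_factory=tuple)

    def genotypes_at(self, generation: int) -> np.ndarray:
        """Per-line diploid genotypes after ``generation`` generations."""
        geno = self.anc_genotypes.copy()
        ev = self.events[self.events["generation_of_origin"] <= generation]
        if len(ev):
            geno[
                ev["site_index"].to_numpy(dtype=np.int64),
                ev["line_index"].to_numpy(dtype=np.int64),
                ev["chromosome"].to_numpy(dtype=np.int64),
            ] = np.array([NUC_INDEX[nt] for nt in ev["mutant_nt"]], dtype=np.int8)
        return geno


@dataclass
class SimResult:
    tables: list[SiteTable]  # one SiteTable per time point
    truth: Truth


def _draw_reads(
    geno: np.ndarray, mean_cov: float, eps: float, rng: np.random.Generator
) -> np.ndarray:
    """Sample per-site A/C/G/T counts for one line and time point.

    ``geno`` is (S, 2) nucleotide codes; returns (S, 4) counts.  Depth
    is Poisson; reads pick a chromosome uniformly and are mis-read with
    probability eps, uniformly over the three other nucleotides.
    """
    S = geno.shape[0]
    counts = np.zeros((S, 4), dtype=np.int64)
    depth = rng.poisson(mean_cov, size=S)
    c0 = rng.binomial(depth, 0.5)
    per_chrom = (c0, depth - c0)
    others = np.array(
        [[y for y in range(4) if y != x] for x in range(4)]
    )  # (4, 3)
    rows = np.arange(S)
    for k in (0, 1):
        src = geno[:, k]
        n = per_chrom[k]
        n_err = rng.binomial(n, eps) if eps > 0 else np.zeros(S, dtype=np.int64)
        np.add.at(counts, (rows, src), n - n_err)
        if eps > 0 and n_err.sum():
            e1 = rng.binomial(n_err, 1.0 / 3.0)
            e2 = rng.binomial(n_err - e1, 0.5)
            e3 = n_err - e1 - e2
            tgt = others[src]  # (S, 3)
            for slot, cnt in enumerate((e1, e2, e3)):
                np.add.at(counts, (rows, tgt[:, slot]), cnt)
    return counts


def _plant_mutations(
    config: SimConfig, anc: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw mutation events per line, chromosome copy and site.

    Each (site, chromosome) pair of each line mutates by the final
    generation G with probability 1 - (1 - mu)^G; conditioned on
    mutating, the generation of origin is truncated-geometric.
    """
    S, L = config.n_sites, config.n_lines
    G = max(config.generations_at_tp)
    mu = config.mu_sim
    expected_per_line = 2.0 * S * G * mu
    if expected_per_line > S / 10.0:
        raise ValueError(
            f"expected {expected_per_line:.0f} mutations per line exceeds "
            f"n_sites/10 = {S / 10:.0f}; mutation process would saturate"
        )
    p_any = -np.expm1(G * np.log1p(-mu)) if mu > 0 else 0.0
    records = []
    for line in range(L):
        k = rng.binomial(2 * S, p_any)
        if k == 0:
            continue
        slots = rng.choice(2 * S, size=k, replace=False)
        site_idx = slots // 2
        chrom = slots % 2
        # inverse-CDF sample of a geometric truncated at G
        u = rng.random(k)
        gen = np.ceil(np.log1p(-u * p_any) / np.log1p(-mu)).astype(np.int64)
        gen = np.clip(gen, 1, G)
        anc_nt = anc[site_idx, line, chrom]
        shift = rng.integers(1, 4, size=k)
        mut_nt = (anc_nt + shift) % 4
        for s, c, t, a_nt, m_nt in zip(site_idx, chrom, gen, anc_nt, mut_nt):
            records.append((int(s), line, int(c), int(t), int(a_nt), int(m_nt)))
    df = pd.DataFrame(
        records,
        columns=[
            "site_index",
            "line_index",
            "chromosome",
            "generation_of_origin",
            "anc_code",
            "mut_code",
        ],
    )
    df = df.sort_values(["site_index", "line_index", "chromosome"]).reset_index(
        drop=True
    )
    return df


def _truth_frame(config: SimConfig, df: pd.DataFrame, line_ids) -> pd.DataFrame:
    out = pd.DataFrame(
        {
            "scaffold": config.scaffold,
            "position": df["site_index"] + 1,
            "line_id": [line_ids[i] for i in df["line_index"]],
            "ancestral_nt": [NUCLEOTIDES[c] for c in df["anc_code"]],
            "mutant_nt": [NUCLEOTIDES[c] for c in df["mut_code"]],
            "generation_of_origin": df["generation_of_origin"],
            "chromosome": df["chromosome"],
            "site_index": df["site_index"],
            "line_index": df["line_index"],
        }
    )
    return out


def simulate(config: SimConfig) -> SimResult:
    """Generate per-time-point count tables plus the truth ledger."""
    ss = np.random.SeedSequence(config.seed)
    n_streams = 2 + len(config.generations_at_tp) * config.n_lines
    children = ss.spawn(n_streams)
    rng_geno = np.random.default_rng(children[0])
    rng_mut = np.random.default_rng(children[1])

    S, L = config.n_sites, config.n_lines
    ref = rng_geno.choice(4, size=S, p=config.base_composition).astype(np.int8)
    anc = np.repeat(ref[:, None, None], 2, axis=2)
    anc = np.repeat(anc, L, axis=1).astype(np.int8)
    het = rng_geno.random(S) < config.ancestral_het_fraction
    if het.any():
        alt = (ref[het] + rng_geno.integers(1, 4, size=het.sum())) % 4
        anc[het, :, 1] = alt[:, None]

    line_ids = tuple(f"L{i + 1:02d}" for i in range(L))
    events = _plant_mutations(config, anc, rng_mut)
    truth = Truth(config, ref, anc, _truth_frame(config, events, line_ids), line_ids)

    tables = _sequence_all(truth, config, children[2:])
    return SimResult(tables=tables, truth=truth)


def _sequence_all(
    truth: Truth, config: SimConfig, streams: Sequence[np.random.SeedSequence]
) -> list[SiteTable]:
    S, L = config.n_sites, config.n_lines
    positions = np.arange(1, S + 1, dtype=np.int64)
    scaffolds = np.full(S, config.scaffold, dtype=object)
    tables = []
    k = 0
    for tp, gen in enumerate(config.generations_at_tp):
        geno = truth.genotypes_at(gen)
        counts = np.zeros((S, L, 4), dtype=np.int64)
        for line in range(L):
            rng = np.random.default_rng(streams[k])
            k += 1
            counts[:, line, :] = _draw_reads(
                geno[:, line, :],
                config.mean_coverage[tp],
                config.error_rate,
                rng,
            )
        tables.append(
            SiteTable(scaffolds, positions, truth.ref_codes.copy(), counts, line_ids=truth.line_ids)
        )
    return tables


def resequence(
    truth: Truth,
    config: SimConfig,
    new_seed: int,
    generations: Sequence[int] | None = None,
) -> list[SiteTable]:
    """Fresh reads from the same evolved genotypes (a replicate run).

    Models re-sequencing the same lines: the mutational history is kept,
    only the sequencing randomness is redrawn from ``new_seed``.  By
    default all configured time points are re-sequenced.
    """
    gens = tuple(generations) if generations is not None else config.generations_at_tp
    cfg = SimConfig(
        n_sites=config.n_sites,
        mu_sim=config.mu_sim,
        n_lines=config.n_lines,
        base_composition=config.base_composition,
        ancestral_het_fraction=config.ancestral_het_fraction,
        generations_at_tp=gens,
        mean_coverage=tuple(config.mean_coverage[: len(gens)])
        if len(config.mean_coverage) >= len(gens)
        else tuple([config.mean_coverage[0]] * len(gens)),
        error_rate=config.error_rate,
        seed=new_seed,
        scaffold=config.scaffold,
    )
    ss = np.random.SeedSequence(new_seed)
    streams = ss.spawn(len(gens) * config.n_lines)
    return _sequence_all(truth, cfg, streams)
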