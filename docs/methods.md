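# Methods

## Data model

Input is a per-site, per-line table of nucleotide read counts
(n_A/n_C/n_G/n_T), the *pro* format, produced either from samtools
mpileup text (`macall pro`) or by the simulator. Base qualities are not
used — all error handling happens through the site-specific error-rate
estimate. Coordinates are 1-based in mpileup/pro and 0-based half-open
in BED masks. Strand is not tracked.

At most two alleles are modelled per site. Reads are conditionally
independent draws given the line's genotype g and the site error rate
ε ∈ [0, 0.75]:

| genotype | P(read = M) | P(read = m) | P(read = each other nt) |
|----------|-------------|-------------|--------------------------|
| MM       | 1 − ε       | ε/3         | ε/3                      |
| Mm       | ½ − ε/3     | ½ − ε/3     | ε/3                      |
| mm       | ε/3         | 1 − ε       | ε/3                      |

The heterozygote allele probability ½ − ε/3 follows from drawing a
chromosome uniformly and mis-reading with probability ε spread evenly
over the three other nucleotides; ε absorbs sequencing, library and
mapping errors alike, which is why it is estimated per site rather
than globally.

## Per-site estimation

Major and minor alleles are the two highest pooled counts (ties broken
in the fixed order A &lt; C &lt; G &lt; T). The free parameters
(P_MM, P_Mm, P_mm, ε) maximise the mixture likelihood over lines. The
optimiser is EM with two latent variables — each line's genotype and
each read's error indicator — so both the E-step and the M-step are
closed form and the ε update is simply the expected error fraction.
Convergence: log-likelihood improvement &lt; 1e-10 or 1000 iterations;
initialisation is fixed (uniform genotype frequencies, ε = 0.01), so
the fit is fully deterministic. If EM stalls below the monomorphic
corner of the parameter space, the corner solution is adopted, which
keeps the full and null models properly nested.

The polymorphism test compares the full fit against the best
single-homozygote model (frequency fixed at 1, ε at its closed-form
MLE) with a likelihood-ratio statistic referred to χ² with 2 degrees
of freedom — the two extra free genotype-frequency parameters.
(Whether a boundary-corrected mixture null would be preferable is a
known open point; df = 2 is this package's declared convention and is
slightly conservative.) Sites with p ≥ 0.05 are treated as monomorphic
downstream (the *SNP gate*): isolated error reads then cannot be
analysed as alleles, which would otherwise veto the site's callability
through the binomial filter. The gate threshold `snp_alpha` defaults
to 0.05.

## Genotype calling and the exact binomial filter

Per line, the genotype posterior over (MM, Mm, mm) multiplies the
fitted genotype frequencies by the multinomial read likelihood; the
ancestral genotype is the consensus (most abundant) posterior call,
with ties voiding the site — conservative, since no principled
tie-break exists. Consensus is computed from the *unfiltered* calls
because the filter itself needs the ancestral genotype as its null.

The filter is a two-tailed exact binomial goodness-of-fit test on the
line's counts of the two alleles, by the method of small p-values:
all outcomes with i + j = n_A + n_a whose probability does not exceed
the observed outcome's (ties included, relative tolerance 1e-12 —
including ties can only enlarge p, i.e. it is the conservative
direction) are summed. The test is conservative, so no
multiple-testing correction is applied. Decision logic:

* heterozygous ancestor: test the het null at α = 0.025; if rejected,
  downgrade to a homozygote only when every read in the line is a
  single nucleotide, else no-call;
* homozygous ancestor: test the hom null at α = 0.05; if rejected,
  test the het null at α = 0.025 and call a heterozygote only when it
  stands **and** both alleles have ≥ 2 reads, else no-call.

The heterozygous α is half the homozygous one because chance deviations
from a 50:50 read split are more likely than from a pure-read
expectation. Under the hom null the success probability is 1 − ε/3 as
the test's binomial form requires (the pair (1 − ε/3, ε/3) sums to 1
over the two-allele outcome space); the alternative reading 1 − ε is
available as `hom_model="complement"` for sensitivity analysis. Lines
with fewer than `min_reads` (default 8; 6 as sensitivity setting)
total reads are never called.

The vectorised pipeline short-circuits only one analytically exact
case: when a line has no alternative-allele reads and the observed
outcome is provably modal ((1 − ε/3) ≥ n·ε/3), every outcome qualifies
for the small-p sum and p = 1 exactly. Everything else goes through
the same enumeration routine the unit tests check against an
independent oracle.

## Site filters and callability

Four independent filters, all accumulated (a verdict lists every
failure): a third/fourth-ranked allele exceeding its error expectation
(one-sided binomial test on reads pooled over lines with ≥ 6 reads,
success probability ε/3 with ε floored at 1e-4 so a zero estimate
cannot make any single read significant; this binomial test is this
package's stand-in for an external high-coverage caller's multi-allele
detection); total pooled coverage outside [min, max] (inclusive
bounds); ε &gt; 0.01 (strict); repeat-mask membership. Default coverage
bounds are [40, 400] (per-line means near 10×; [40, 500] fits ~14×);
for simulated data use bounds bracketing the expected pooled depth —
the validation suite uses [140, 420] at 20× per line over 14 lines
(pooled mean 280, Poisson SD ≈ 17).

A site is *callable* when it passed the filters, every line has a
filtered call from ≥ min_reads reads, and the ancestral genotype is
homozygous for the reference nucleotide (guarding against reference
bias). Candidates are nucleotides in exactly one line's call that are
absent from the ancestor; sites where two or more lines carry a mutant
nucleotide are discarded outright. Each time point is an independent
run; the ancestral genotype is re-inferred per time point.

A consequence of the decision tree worth noting: at a
homozygous-ancestor site a rejected line can only be re-called as a
heterozygote, so homozygous mutants are unreachable through the
filter. They require two hits at one site and are vanishingly rare in
MA data; the scalar `identify_mutations` operation nevertheless admits
them if presented with such a call.

## Assessment and rates

Two candidates match when they share scaffold, position and mutant
nucleotide — two different alleles at one position are distinct
events. Sharing rates for an (earlier, later) time-point pair divide
within-line / cross-line matches by the earlier candidates whose site
is callable later; the unconfirmed rate conditions on the line having
a genotype call at both time points. Any rate with a zero denominator
is NA, never 0. Within-line confirmation requires full candidate
status (including exclusivity) at both time points.

μ = m/(2NTg) with Poisson SE √(μ/(2NTg)); conditional rates divide
per-type counts by callable sites with the matching ancestral
nucleotide, counted with multiplicity across time points to mirror the
pooled numerator. Ts/Tv sums the four transition-type rates over the
eight transversion-type rates; AT bias is the G/C→A/T rate sum over
the A/T→G/C sum. The mean over pairwise estimates is arithmetic, with
SE = √(Σ SEᵢ²)/k — the standard error of a mean of independent
estimates; no established alternative combination reproduces every
published summary SE, so this formula is declared rather than
inferred. Display rounding is 3 significant figures; all internal
arithmetic is full precision.

## Simulator

The generator works at the read-count level, emulating a 14-line
diploid MA design sequenced at three time points (defaults: 82, 159
and 188 generations at mean per-line coverages 10.8, 13.8 and 10.0,
matching a moderate-coverage Daphnia design). Mutations arise per
site, per chromosome copy, per generation with probability `mu_sim`,
convert the allele to a uniform alternative, and persist; a run
refuses configurations expecting more than n_sites/10 mutations per
line (saturation). Depths are Poisson; reads pick a chromosome
uniformly and are mis-read with probability `error_rate` (default
3e-4, a typical per-site error-rate level for Illumina data after
mapping) — exactly the error model the caller assumes. The ancestor is
heterozygous at a fraction `ancestral_het_fraction` of sites (default
1e-3, the order of magnitude of D. pulex nucleotide diversity).
`resequence` redraws reads from the same evolved genotypes, modelling
a replicate library of the same lines. All randomness derives from
one seed through per-(time point, line) child streams, so outputs are
byte-reproducible.

Deliberately not modelled: read-level artefacts (mapping, duplicates,
chimeras), coverage autocorrelation along the genome, indels and
repeat-induced mismapping. Passing tests on this generator therefore
validate the statistical machinery — estimation, testing, callability
bookkeeping, rate arithmetic — not robustness to mapping artefacts,
which on real data are handled upstream of the count table.

## Validation problem sizes

The test suite validates parameter recovery on five independent
synthetic studies of 14 lines × 10⁵ sites (g = 100, μ = 10⁻⁶, 20×
coverage, ε = 10⁻³, seeds fixed), each with a re-sequenced replicate:
the mean recovered rate must sit within three standard errors of the
generating rate, cross-line sharing must be exactly zero and pooled
within-line sharing at least 0.9. A separate three-time-point run at
2 × 10⁴ sites and the default design checks the time-series statistics
end to end. Exact-test equivalence with an enumeration oracle is
checked exhaustively for all read totals ≤ 30 at ε ∈ {0, 10⁻³, 10⁻²}.

## Known limitations

* The two-allele model cannot represent genuine tri-allelic sites;
  they are filtered, not called.
* Detection losses at mutation-carrying sites (a skewed read split
  failing the het test, or a stray error read no-calling a bystander
  line) remove the site from both numerator and denominator but remove
  mutations preferentially, giving a small downward bias in μ̂ — about
  5% at 20× and ε = 10⁻³, well inside one standard error at the
  validated problem sizes, but growing with ε and depth.
* The per-site ε estimate is noisy at single-site resolution
  (deliberately so, to catch locally problematic sites); it is not a
  calibrated genome-wide error rate.
* Back mutations and multiple hits are modelled in the generator only
  as overwrites and are negligible at supported settings.
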