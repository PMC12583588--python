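# Methods

This note documents the models, the parameters that matter, the synthetic
data generator, and the numerical and design choices behind `enhevo`. It
states nothing the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinate model

All coordinates are 0-based half-open; 1-based inclusive input
(RepeatMasker `.out`) is converted at the I/O boundary and nowhere else.
Chromosome names are taken verbatim. Strand is carried as an annotation but
ignored by all overlap logic — only the motif scanner interprets strand,
internally, by scoring the reverse complement. Interval algebra (merge,
union bp, per-query covered bp, complement) runs on sorted numpy arrays and
is cross-checked in the tests against a per-base bitmap oracle on ≤ 10 kb
chromosomes.

## Alignability classification

Cross-species comparisons consume *interval sets*: per outgroup genome, the
merged set of human bases that align (`aligned`) and its lineage-specific
complement (`gaps`). This makes every classification a pure function
testable on fixtures; producing the maps (lift-over chains, whole-genome
alignment) is out of scope.

Rules, with every tie resolved by the ≥ reading of the printed threshold:

| call | rule | default |
|---|---|---|
| static | aligned fraction ≥ minmatch in chimp **and** macaque | 0.97 |
| intermediate | ≥ minmatch in chimp only | 0.97 |
| rapid | neither | — |
| quasi-ortholog | macaque aligned fraction ≥ relaxed threshold | 0.5 |
| TE gained (loose) | any gap overlap (≥ 1 bp) | — |
| TE gained (strict) | gap overlap ≥ 90% of copy length | 0.9 |
| TFBS gained | 100% contained in the gap union | — |
| TFBS TE-derived | 100% contained in a single TE copy | — |
| peak shared / novel | ≥ 50% aligned / else > 50% gap / else ambiguous | 0.5 |
| peak Alu/pERV-derived | ≥ 50% of peak bases from that biotype (union) | 0.5 |

Fraction computations use the union of merged intervals. A peak exactly 50%
aligned is *shared* because the shared rule is stated with ≥ and evaluated
first. A motif nested in several TE copies is attributed to the shortest
containing copy (the most specific element); the choice is a tie-break the
underlying data rarely exercises, and a fixture test pins it down.

## Divergence statistics

The point-substitution rate of a region against an outgroup is measured on
gapped pairwise alignment blocks: columns where either string holds a gap
or an ambiguity code leave the denominator; comparison is case-insensitive;
multiple blocks per region are pooled (sums of mismatches and of gap-free
columns), not averaged per block, which is robust to fragmented alignments.
A region with zero usable columns reports a missing rate, never 0.

The distance-to-gap profile bins every mismatch (and, for the density
denominator, every gap-free column) by its alignment-column distance to the
nearest gap column, with half-open (lo, hi] bins. Mismatches in blocks
without any gap are tallied separately and excluded from the binned
densities rather than given an infinite distance. Distances are measured in
alignment columns; in gap-free neighbourhoods these coincide with genomic
bp. Track summaries (e.g. conservation scores) are base-weighted means over
covered bases only, with the covered fraction reported so callers can
filter; missing data is never imputed as 0.

## TE-subfamily enrichment

Counting: a TE copy counts toward a region group when its overlap with the
merged regions is ≥ 10 bp; coverage sums the overlapping bases of every
intersecting copy, counted or not.

Two one-sided (upper) tests probe complementary aspects:

* **hypergeometric on copies** — universe = all TE copies genome-wide,
  successes = the subfamily's copies, draws = copies counted in the
  regions, observed = the subfamily's counted copies;
* **binomial on coverage** — n = region bp, success probability = the
  subfamily's genome bp density, observed = its bp inside the regions.

p-values are BH-adjusted across subfamilies within a region group
(α = 0.01). The choice of *copies* as the hypergeometric universe (with the
bp-based binomial as the complementary test) is a documented assumption;
the coverage test is intentionally sensitive to clumped placement, which is
exactly what the shuffle controls exist to absorb.

Controls: regions are shuffled (default 1000 replicates) preserving the
exact length multiset, placed uniformly over the genome minus the real
regions, overlaps among placements allowed (the default behaviour of
genome shufflers). Each replicate is grouped two ways — (i) resampled to
mirror each real group's count and length distribution via greedy
nearest-length matching, and (ii) re-classified by the alignability rules
applied to the real regions. A subfamily's final verdict is *enriched* only
if both adjusted real p's are < α **and** in each control scheme it reaches
significance in ≤ 5% of replicates (the tolerance). The tolerance is read
per replicate — the fraction of control replicates in which the subfamily
is significant — the most literal reading of the rule; an alternative
reading (≤ 5% of subfamilies) exists and was not implemented.

On the fully synthetic cohort the re-classified control fires deliberately:
with gaps equal to young TE copies, any shuffled region classified
"dynamic" must overlap a young TE, so group-anchored subfamilies are
rejected there. That is the control doing its job (catching composition
bias induced by the classification itself); calibration and power are
therefore measured on a uniform-placement scenario
(`gen_enrichment_scenario`: one 500 kb chromosome, 8 subfamilies × 200
copies of 50 bp, 100 regions of 800 bp, planting at 3× genome density).
Short copies relative to regions keep the binomial null close to nominal.

Sequence-class coverage (`coverage_by_class`) resolves overlapping
annotations per base with priority to the shortest overlapping element,
making the classes disjoint so Alu + pERV + pLINE + pDNA + SVA + ancient +
non-TE sums to exactly 100%.

## Motif engine

Scores are log2 odds against an i.i.d. background (default uniform,
overridable), with column probabilities
(count + pseudocount·bg)/(colsum + pseudocount) and pseudocount 0.8
distributed by background — finite log-odds whenever the pseudocount is
positive. Windows containing ambiguous bases are dropped, never partially
scored.

Exact p-values: per-column log-odds are rounded to an integer grid whose
step spans the total score range in 10⁴ bins; column distributions are
convolved under the background to give the full pmf, and a query score maps
to the nearest grid point of the right tail. The DP equals exhaustive
enumeration over all 4^W words for W ≤ 8 at any threshold separated from
the achievable scores by more than the grid resolution (asserted in the
tests); p is right-continuous, decreasing, 1 at or below the minimum
achievable score.

Consensus matching treats all positions × strands of one matrix on one
query as the BH family; the best q decides stringent (q < 10⁻⁴),
permissive (q < 10⁻³) or none. A *bound* motif must be 100% contained in a
single peak interval — peak sets are merged upstream when factors are
pooled, so the single-peak rule is not restrictive, and the call is
monotone under peak growth. Group-level motif contrasts use a two-tailed
hypergeometric (twice the smaller tail, capped at 1), with a 0.5 Haldane
correction applied to the odds ratio only when a cell is zero (flagged).

Binding affinity is the raw maximum log-odds over positions and strands
(not a normalized 0–1 score); Δ = max_a − max_b with trajectory increasing
(Δ ≥ +2 bits), decreasing (Δ ≤ −2) or neutral. Allele-effect comparisons
substitute each allele into the motif-bearing window (motif ± matrix
width); when neither allele reaches an optional minimum score the
comparison is flagged no-motif and forced neutral.

## Selection scan

Exactly three populations are required. Per SNP:

* **FST** — Reynolds' coancestry estimator a/(a+b) for biallelic loci in
  its haploid gene-count form (r = 2, no within-individual component):
  n̄ = (n₁+n₂)/2, n_c = 2n₁n₂/(n₁+n₂), p̄ the weighted mean frequency,
  s² = [n₁(p₁−p̄)² + n₂(p₂−p̄)²]/n̄,
  a = (n̄/n_c)[s² − (p̄(1−p̄) − s²/2)/(n̄−1)],
  b = (n̄/(n̄−1))(p̄(1−p̄) − s²/2). Its large-sample limit is
  (p₁−p₂)²/(p₁(1−p₂)+p₂(1−p₁)). Negative estimates clip to 0, estimates
  ≥ 1 to 1−10⁻¹²; loci monomorphic for the same allele in both populations
  return 0. Multi-locus summaries use Σa/Σ(a+b).
* **PBS** — T = −ln(1−FST); PBS_A = (T_AB + T_AC − T_BC)/2, clipped at 0
  for ranking with the raw value retained (raw PBS_A + raw PBS_B = T_AB
  to 10⁻¹²).
* **empirical p** — (1 + #{background ≥ value})/(N+1) against the
  population's common variants (per-population MAF > 5%), ties counting as
  ≥. The +1 keeps p strictly positive for Fisher's method; at genome-scale
  N the difference from the literal percentage is negligible. Backgrounds
  are per population and per dataset, never pooled.
* **combined p** — Fisher's method on (external per-variant p, empirical
  PBS p): survival of χ²(4 df) at X = −2(ln p₁ + ln p₂) = e^(−X/2)(1+X/2).

Per enhancer, the family is (overlapping SNPs × 3 populations); the Sidak
adjustment 1−(1−p_min)^m is computed as −expm1(m·log1p(−p_min)) and is
accurate to better than 10⁻⁹ relative for p_min ≥ 10⁻³⁰. BH across tested
enhancers at 5% FDR sets the positive-selection flag; enhancers without
SNPs are excluded from the FDR universe and reported untested. SNP labels
use the minimum combined p across populations: < 0.01 PS-SNP, > 0.5
neutral, else unlabeled — the minimum is used for both rules for symmetry.

## Synthetic cohort

One integer seed fans out to per-component child streams by fixed offsets,
so adding a generator never perturbs the others; every artefact is a pure
function of (config, seed).

* **Genome & TEs.** Random background sequence (default 2 × 200 kb);
  each subfamily has a consensus (default lengths 200–600 bp), a biotype,
  an age clade (ancient, shared-primate, great-ape, human) and a per-copy
  substitution rate (1–20%, older subfamilies more diverged); copies are
  placed without overlap. Default landscape: ~200 copies across 7
  subfamilies spanning Alu/pERV/pLINE/SVA/ancient.
* **Alignability.** Copies younger than an outgroup's divergence are
  exactly the gaps for that outgroup (great-ape + human ages for macaque,
  human for chimpanzee); optional background gaps model alignment noise at
  a configurable rate per 100 kb (0 by default, so planted labels are
  exactly recoverable).
* **Enhancers.** 150 regions of 500–1500 bp in proportions 50/42/8%
  static/intermediate/rapid (the ratio of the three classes in the
  motivating data). Dynamic enhancers are anchored on a young TE copy with
  > 3% of their length inside it, which simultaneously encodes the class
  label in the alignability maps and the group-dependent TE density;
  static enhancers avoid young copies entirely.
* **Motifs & peaks.** A consensus-planted motif word per chosen subfamily
  (default an NF-κB-like 10-mer at offset 120 in the Alu/pERV consensus
  sequences) gives every copy a ground-truth instance; peaks cover a
  configurable fraction of instances (default 0.6) with a ±50 bp flank.
* **Population panel.** Balding–Nichols: ancestral p ~ U(0.05, 0.95), each
  population's frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F) with drift
  F = 0.05 per population (expected pairwise differentiation ≈ F, giving
  the FST estimator a parameter-recovery target); SNPs below 5% MAF in all
  populations are redrawn. Frequencies are population frequencies — no
  binomial sampling layer — so estimator checks at moderate n expect the
  finite-sample correction to overshoot slightly; calibration tests use
  large panel sizes. Sweeps (default 20 of 2000 SNPs): +0.4 frequency
  shift, clipped, in one designated population; external selection
  p-values are Uniform(0,1) under the null and Beta(0.1, 10) at sweep
  sites, drawn independently per population. The uniform null is an
  idealization of genealogy-based p-values, recorded as such.
* **Disease layer.** A core block of 20 genes each in 4 of 10 diseases
  (≥ 30% sharing) against a background of genes in 1 disease; links
  connect ~30% of enhancers to core genes; ChIP peaks reuse the motif peak
  model.

What the generator does **not** emulate: haplotype structure and LD (sweeps
are frequency shifts, not coalescent simulations), indel-driven alignment
gaps inside TE copies, target-site duplications and 5'-truncation of real
retrotransposon insertions, non-uniform genomic background composition,
and correlated disease annotations. Passing tests therefore demonstrate
the correctness and calibration of the *methods*, not properties of real
genomes.

## Problem sizes

Chosen so the whole suite and the acceptance script each run comfortably on
one CPU: toy pipeline 2 × 400 kb with 200 enhancers, 1000 SNPs and 200
shuffles; enrichment calibration/power 100 seeds × 100 shuffles on the
uniform scenario; selection calibration/power 100 replicates of 1000–2000
SNP panels; DP-vs-enumeration up to W = 8 (65 536 words). The standard
shuffle count remains 1000 by default in the pipeline configuration; any
override is echoed into the run manifest.

## Known limitations

* The binomial coverage test treats bases as independent; with copies long
  relative to regions its null is anti-conservative. The shuffle tolerance
  is the designed mitigation, and the calibration scenario uses short
  copies; interpret coverage p-values at genome scale through the verdict,
  not alone.
* The PWM p-value grid introduces discretisation of order (score range)/10⁴
  per column sum; thresholds within that distance of an achievable score
  can move p by the probability of the words at the boundary.
* `empirical_p` includes the query variant in its own background when it is
  common, making p conservative by ~1/(N+1).
* The enrichment verdict on the fully synthetic cohort is intentionally
  conservative (see above); use the uniform scenario to study power.
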