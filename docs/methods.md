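# Methods

This note documents the models and procedures implemented in `mitopopcons`,
the assumptions behind them, the parameters that matter, and the design
choices made where the design was genuinely open.

## 1. The detection problem

At a functional site, purifying selection removes new mutations before they
can segregate or fix, depressing both between-species divergence and
within-species diversity. With an ultradeep population sample of a short,
non-recombining genome (the regime of deep human mtDNA collections:
~16.6 kb, tens of thousands of genomes, a segregating mutation on roughly
every other base pair), the per-site count of distinct alleles
`a_i ∈ {1..4}` becomes informative enough to read constraint at almost
base-pair resolution. The package implements the full chain from this
observation to called functional elements, and a generator of synthetic
data with known truth so every step can be validated quantitatively.

## 2. Replication asymmetry and the D_ssH covariate

Mitochondrial-like genomes replicate asymmetrically: leading (heavy-strand)
synthesis starts at O_H; the displaced parental heavy strand stays
single-stranded until lagging (light-strand) synthesis, initiated at O_L
once the leading fork arrives there, passes back over it. Single-stranded
DNA deaminates and mutates faster, so the duration of single-strandedness
is a mutation-rate covariate that would otherwise masquerade as relaxed
constraint.

With equal unit fork speeds, leading distance `d` from O_H and origin
separation `D`:

* major arc (`d ≤ D`): single-stranded from time `d` until the lagging fork
  returns at `D + (D − d)`, so `D_ssH = 2(D − d)`;
* minor arc (`d = D + y`): the lagging fork travels the other way round and
  arrives at `D + (L − y)`, so `D_ssH = max(L − 2y, 0)` — zero where the
  lagging fork wins the race.

The cited single-strandedness model is reconstructed from this geometry;
no closed formula was available to copy, so the expression is verified in
the test suite against a discrete-time two-fork simulation, exactly, at
every site of toy genomes. Whether minor-arc sites should receive the
wrap-around value or be excluded is not decidable from first principles;
both behaviors exist behind `ReplicationModel(minor_arc="wrap"|"exclude")`,
with "wrap" the default. Control-region sites are excluded from all D_ssH
analyses (the interval is taken from the annotation record with class
`control`).

The correction itself is a Poisson log-link GLM of allele counts on D_ssH
(statsmodels IRLS, relative-deviance tolerance 1e-8, max 100 iterations),
fitted on all non-control sites. The response is the raw allele count 1..4,
taken literally as the Poisson variable rather than `count − 1`. Residuals
default to deviance residuals (Pearson and response are selectable),
matching the default residual convention of the common statistical
environments. A constant covariate leaves the slope unidentified; the fit
degrades to intercept-only with a warning rather than erroring.

## 3. Correlation analyses

All correlations are Spearman with midranks — essential, because allele
counts take four values and ties dominate — and a two-sided p from the
t-approximation with n − 2 df. With n ≈ 16,569 the approximation is
accurate and permutation p-values would add nothing; reported p-values are
floored at 2.2e-16 (the raw value is kept on the result object). The sign
convention is fixed throughout: allele counts are correlated against the
*negated* phyloP-like score, so constraint produces positive rho.

Windowed correlations use arithmetic means in 10-bp adjacent windows by
default (5-bp sliding windows for fine-scale profiles); masked sites are
excluded from window means, a trailing partial window is kept only if at
least half a window of sites remains, and windowing is linear by default
with circular wrap-around behind a flag.

Per-gene tables carry raw per-gene p-values (no multiple-testing
correction), plus a clearly marked Benjamini–Hochberg column as an
extension for users. Codon classes are derived from the annotated protein
genes and the reference sequence: codons are read 5'→3' on the coding
strand, position 2 is the nonsynonymous class, position 3 is 4-fold
degenerate iff the codon prefix admits all four third bases with one amino
acid under the vertebrate mitochondrial code (translation table 2, via
biopython); partial trailing codons are skipped with a warning and
overlapping protein annotations resolve by record order.

## 4. The mitoPopCons HMM

A two-state HMM over the genome-wide allele-count sequence (monomorphic
fill = 1, so every position emits). The transition matrix is *fixed*, not
learned: the reference protocol borrowed it from a divergence-based
conserved-element HMM whose actual values are not recoverable, so the
default here is symmetric with stay probability 0.99 — expected state runs
of 100 bp, the scale of the elements the method is meant to call — and a
helper derives a matrix from the phastCons-style (expected element length,
expected coverage) parametrization instead. The initial distribution is the
stationary distribution of the fixed matrix (unstated in the protocol;
stationarity is the standard neutral choice) and is not updated.

Training is emission-only Baum–Welch: the E-step is the scaled
forward–backward recursion; the emission M-step re-estimates the 2×4 matrix
from expected symbol counts, floored at 1e-10 to keep EM away from
absorbing zeros; the transition M-step adds `pseudocount_scale ×
fixed_transition` pseudocounts to the expected transition counts. The
freezing bound is drift ≤ T / pseudocount_scale per entry: with T = 16,569
a scale of 1e12 (the default) keeps the matrix within ~2e-8 of its fixed
value, comfortably inside the 1e-6 contract the tests enforce. Ten random
restarts (emission rows drawn from a symmetric Dirichlet, restart r seeded
`seed + r` and recorded for reproducibility) guard against poor local
optima; the restart with the highest log-likelihood wins. The state with
the higher probability of emitting monomorphic sites is labeled functional,
and maximal Viterbi runs of that state are the called elements (posterior
marginals are available for inspection but are not used for calling).
Viterbi ties break toward the lower state index, deterministically; the
state-swap symmetry of element calls therefore holds whenever the optimum
path is unique.

The chain is linear (no circular wrap in the HMM), matching standard
practice for mitochondrial browser tracks; the genome's circularity enters
only through coordinate handling and the permutation scheme. The
forward/backward/Viterbi recursions are hand-unrolled for the two-state
chain as tight scalar loops, which keeps a full-genome training with ten
restarts around three seconds and the downsampling power analysis cheap,
without compiled extensions.

## 5. Element evaluation

Overlap between two element sets is counted in base pairs of intersection.
"Permuting the coordinates" of the calls is ambiguous in the reference
protocol; the default scheme places each element independently at a uniform
start on the circular genome, preserving lengths (placed elements may
overlap each other) — the simplest literal reading — with a
spacing-preserving single-rotation scheme as the alternative. Both are
seeded. The empirical p uses the +1 correction, `p = (1 + #{perm ≥ obs}) /
(1 + N)`, never exactly zero, and is reported as `< 1/(N+1)` when no
permutation reaches the observed overlap; N defaults to 10,000.

Summaries report element count, mean length, the fraction of element bp
falling outside genes, and the fraction of genic bp recovered. "Genic"
means the union of protein/tRNA/rRNA spans; the control region counts as
genic only behind a flag, since the reference convention is unstated.

The power analysis requires sample-level allele counts (tables carrying
only allele counts are refused, mirroring the fact that only the
frequency-bearing dataset supports downsampling): at each sample size in
the grid 100, 200, …, 1800 plus 1,864 — the minimum sample size of the
frequency-bearing collection — each site's counts are redrawn without
replacement (multivariate hypergeometric), alleles recounted, the HMM
retrained under the identical fixed-transition/restart protocol, elements
called, and power scored. Within a replicate the draws are nested by
default (the subsample at n is drawn from the subsample at the next larger
size, so observed alleles at n are a subset of those at any larger n): this
common-random-numbers design removes between-size sampling noise from the
curve, leaving the trend itself; independent per-size draws are available
behind a flag. The power metric is base-level recall of
reference-constrained bp (the reference protocol does not state its
metric); precision and F1 are computed alongside.

## 6. The synthetic-data generator

The generator is a deliberate caricature, not a coalescent. Sites are
independent; the per-site number of segregating mutations is
`m_i ~ Poisson(μ_i)` with

```
μ_i = θ_neutral · (1 − c_i) · exp(dssh_effect · D_ssH(i) / L)
```

where `c_i ∈ [0, 1]` is the true constraint; each mutation's derived-allele
sample count follows the neutral spectrum `P(k) ∝ 1/k`; distinct alleles
are `min(1 + m_i, 4)`. Real mtDNA sites share one non-recombining genealogy
and a strongly transition-biased, hotspot-ridden mutation process; the
analyses under test treat sites marginally, so independent sites give
clean, assertable statistics (Poisson zero-class, coupling monotonicity)
at the cost of realism in linkage and in the site frequency spectrum's
shape.

Constraint acts twice, so both signals of selection exist in the synthetic
data: it thins μ (the SNP-density signal), and at strongly constrained
sites (c > 0.5) derived counts are drawn from the spectrum truncated at its
0.9 probability quantile. For the 1/k spectrum that quantile sits near
`k_max^0.9`, well below half the sample, so truncation removes the
high-frequency tail and with it the high-MAF variants — selection holding
deleterious alleles rare (the MAF signal). Divergence tracks are coupled to
the same truth: negated-phyloP-like `= scale·(1 − c_i) + N(0, sd)`
(defaults 2.0 and 0.5), and a deterministic conservation probability
`logistic(slope·(c_i − 0.5))` (slope 8). No attempt is made to emulate a
phyloP null distribution, and divergence is *not* coupled to D_ssH — so the
synthetic D_ssH–divergence correlation is null, unlike real data where the
mutation gradient moves both.

The default layout tiles the 16,569-bp circular genome with an mtDNA-like
mosaic: a 1,122-bp control region wrapping the coordinate origin (stored as
two records sharing a name), 2 rRNAs, 22 tRNAs and 13 protein genes with
realistic lengths, one protein gene on the minus strand, and the small
intergenic remainder. Constraint defaults are essentially two-level —
tRNA/rRNA 0.9; protein codon positions 1 and 2 and non-4-fold third
positions 0.9; 4-fold third positions 0.1; control region 0.2; intergenic
0 — because the segmentation under test is itself a two-level method;
intermediate constraint profiles are configurable but are not the default
study condition. `θ_neutral = 1.8` then yields ≈ 0.54 expected segregating
mutations per site genome-wide, the ultradense regime the method targets.
`dssh_effect = 0.3` (log-rate units per D_ssH/L) gives a modest but
removable rate gradient. Sample size defaults to 16,411 chromosomes.

True functional elements are the maximal runs with `c_i` above a threshold,
default 0.05: any nonzero purifying constraint marks a site as part of a
functional element, which keeps whole protein genes — including their
nearly neutral 4-fold sites — single truth elements. A higher threshold
would fragment truth into sub-codon runs that no 100-bp-scale two-state
segmentation could (or should) reproduce at base level.

What passing tests on this generator do **not** show about real data: per
gene, constraint here is constant within RNA genes, so synthetic per-gene
correlations are driven almost entirely by protein genes' internal
codon-position contrast — real RNA genes show strong per-gene correlations
because real constraint varies within them; the frequency spectrum has no
population growth, so real samples are far more singleton-heavy; and there
is no recurrent-mutation hotspot structure beyond the smooth D_ssH
gradient.

## 7. Study conditions for the power analysis

Under the default dense regime, detection saturates: the
constrained/neutral emission contrast is so strong that even 100
chromosomes recover essentially everything, and the power curve is flat.
The sample-size question is only meaningful where detection is
sample-limited, so the power experiment (`power_study_config`) uses its own
conditions: ~58 scattered fully constrained elements (c = 1) with lengths
cycling over 50..120 bp, separated by 200-bp neutral gaps,
`θ_neutral = 0.12`, and n = 1,864 chromosomes (the grid's full size). Full
constraint keeps element evidence a clean monomorphic run at every sample
size, so the curve isolates the neutral-side information — the number of
background variants observable in a subsample, which grows like log n (the
classic harmonic-number growth of segregating sites under the 1/k
spectrum). The length spectrum matters because the whole grid spans only a
~1.6× range of that effective information: a single element size crosses
its Viterbi detection threshold almost at one point and the curve becomes
a step, while a spread of lengths makes different elements detectable at
different sample sizes, so aggregate base-level recall climbs smoothly
(≈ 0.72 at n = 100 toward ≈ 0.96 at n = 1,864), reproducing the
qualitative logarithmic power law. Two designs that fail instructively:
partially constrained elements (c = 0.9) make the curve peak mid-grid —
at large n the elements' own rare interior variants erode the Viterbi
calls — and equal-length c = 1 elements saturate the curve by n = 200.
Many small elements, rather than one genic block, make recall an average
over dozens of quasi-independent detection events and hence a smooth
function of sample size.

## 8. Coordinate liftover

Positions are mapped between two reference dialects (e.g. a classical
reference numbering vs. a genome-assembly chromosome) by one global
pairwise alignment with affine gaps — two sequences need no external
multiple-alignment program. Scoring defaults: match +1, mismatch −2, gap
open −5, gap extend −1 (a length-ℓ gap costs `open + ℓ·extend`); `N`
matches nothing, itself included, so assembly placeholder bases cannot
anchor the alignment. The aligner is biopython's `PairwiseAligner`
configured with a custom ACGTN matrix; tests verify its optima against an
exhaustive enumeration of alignments on short strings. The resulting
per-position map is strictly increasing over defined positions; bases
deleted in the target map to `None`. No alignment parameters were available
to copy from the reference protocol; these defaults are explicit choices.

## 9. Numerical and I/O conventions

Internal coordinates are 0-based half-open everywhere; SNP tables and
fixedStep wiggle are 1-based on disk and converted at the boundary, BED and
bedGraph are native 0-based half-open. Insertion/deletion rows in SNP
tables are skipped with a warning (the analysis concerns SNPs only);
more than four distinct alleles is impossible by alphabet and the reader
caps defensively. Forward/backward use per-step scaling (no underflow at
T = 1e5); EM stops when the log-likelihood gain drops below 1e-6 (default)
or at 500 iterations. All stochastic stages take explicit seeds; the
pipeline derives stage seeds by fixed offsets from one master seed, and
rerunning any stage with the same configuration and seed is byte-identical.

## 10. Problem sizes

The test suite and the acceptance script run everything at the sizes the
analyses are designed for: full 16,569-site genomes for training,
correlation and end-to-end checks; 15,000 sites for GLM recovery; the full
100..1,864 downsampling grid with 3 replicate draws per size; 10,000
permutations for the headline overlap test and N = 199 × 200 replicates for
the calibration check; brute-force oracles run at T ≤ 12 (HMM paths) and
length ≤ 8 (alignments) where enumeration is exact.
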