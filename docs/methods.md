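# Methods

## The model

MeDIP-seq coverage is treated as count data throughout: no
methylation-level (beta-value) estimation is attempted. Counts of reads
in a 100-bp window for pool *j* are modelled as negative binomial with
mean μⱼ proportional to the pool's library size and a **common
dispersion** φ shared across windows (variance μ + φμ²). The two
comparison groups each contribute replicate pools (three in the default
study, mirroring the pooled-sperm design with three technical pools per
treatment group).

### Normalization

Per-pool scale factors bring every library to the geometric mean of the
library sizes (`total-count` method): factorⱼ = geomean(L)/Lⱼ. A
trimmed-mean-of-ratios variant (`tmm`, 30% two-sided trim on
per-window proportion ratios against the row geometric mean) is
available behind the same contract for data with composition bias; on
clean simulated data the two agree to ~1%.

### Dispersion estimation

For each window and each group with ≥ 2 replicate pools, the normalized
counts yield the moment statistic (s² − μ̂)/μ̂², whose expectation under
the NB model is φ. The default estimator is the **mean** of this
statistic over all windows with nonzero group mean, clamped at zero.
With tens of thousands of windows the mean is nearly unbiased even at
three replicates (simulations at depth 100 recover φ = 0.05 as 0.049
and φ = 0.2 within [0.18, 0.19]). A median variant is provided but not
default: the small-sample distribution of s² is strongly right-skewed,
so the median sits well below φ at three replicates (≈ 0.03 for a true
0.05), and feeding that underestimate to the exact test makes it
anti-conservative — null simulations then show ~10% of windows below
p = 0.05 and occasional null windows below the 10⁻⁷ seed threshold.
Designs with no replicates in either group (the pairwise epiallele
comparisons) must supply a fixed φ; the default there is 0.1.

### The conditional exact test

Replicates within a group are summed after normalization (the
normalized counts of a group are again NB with size scaled by the
number of pools, so group-sum collapsing is exact under the common-φ
model; the replicate treatment is declared here because count-based
pipelines differ on it). Conditional on the window total n = a + b,
the control sum a follows

* Binomial(n, π), π = n₁/(n₁+n₂), when φ = 0 (after normalization all
  pools share one effective library size, so π depends only on the
  group sizes);
* BetaBinomial(n, n₁/φ, n₂/φ) when φ > 0 — the conditional law of one
  NB variate given the sum of two with a common success probability.

The two-sided p-value follows the minimum-likelihood convention: the
sum of probabilities of all outcomes no more probable than the one
observed (a doubled-smaller-tail option exists; for the symmetric
designs used here the two rules coincide). Windows with zero total get
p = 1, never NA, so interval arithmetic downstream is total. When the
observed outcome is the conditional mode the p-value is exactly 1.
Equal-probability ties are grouped with a relative tolerance of 10⁻¹²
so that floating-point noise cannot split a tie. The φ = 0 path matches
an exact-rational enumeration oracle to < 10⁻¹² for all totals ≤ 50.

No window-level multiple-testing correction is applied — region calling
gates on the raw thresholds below — but a Benjamini–Hochberg column is
emitted for information.

## DMR assembly

A window with p below the seed threshold (default 10⁻⁷) nucleates a
region. Any window with p below the extension threshold (default 0.1)
within 1000 bp (`max_gap`) of the growing region is absorbed and
itself extends the search frontier; the process iterates to a fixpoint,
and regions whose closures touch merge. "Within 1000 bp" is measured
edge-to-edge (region boundary to nearest window edge) — the only
reading that yields a well-defined fixpoint. Because absorption is
transitive, the fixpoint equals a chain decomposition of the
extension-candidate windows (consecutive candidates ≤ max_gap apart
chain together; a chain survives iff it contains a seed), which is what
the implementation computes; a literal grow-to-fixpoint oracle is kept
in the test suite and agrees on randomized p-vectors. A gap of exactly
`max_gap` is absorbed (≤, not <).

DMR boundaries snap to window boundaries, so lengths are multiples of
100 bp except at chromosome ends. The multi-site filter
(`min_significant_windows = 2`) defines the stringent, reproducible
set. Reported statistics per DMR: window span, number of seed windows,
minimum p (ties broken leftmost), CpG count and density per 100 bp
from the reference. Written tables use 1-based inclusive starts; BED
output stays 0-based half-open. The threshold sweep reports, per seed
threshold, the number of regions containing ≥ 1 and ≥ 2 seed windows;
"all windows" counts merged regions, not raw windows, and since the
extension threshold stays fixed the counts are nested and monotone in
the threshold.

## Cluster scan

The over-representation scan is a declared construction (the
clustering literature it emulates does not fix parameters): a window of
`scan_width` (default 2 Mb) slides in steps of half its width; the
member count at each position (DMRs by midpoint) is scored against
Binomial(N, width/genome size) where N is the genome-wide DMR count;
positions pass at BH-adjusted p ≤ 0.05 with ≥ 3 members and merge into
maximal, non-overlapping cluster intervals widened to cover their
members. Density is genome-wide, not per chromosome, deliberately: a
repeat-rich chromosome arm that accumulates DMRs should register as a
cluster rather than re-normalize itself away. All four knobs are
config-exposed.

## Epiallele variability

Within a treatment group, every pool pair is tested 1-vs-1 with the
fixed dispersion (default φ = 0.1) and the same region-calling rule;
the union of pairwise DMRs (overlapping intervals merged, per-pair
provenance retained) is the hypervariable set. A structural limitation
worth knowing: the beta-binomial conditional law at φ = 0.1 has a
depth-independent variance floor, so a pool-private fold change of 8
saturates near p ≈ 2×10⁻⁵ and can never cross the 10⁻⁷ seed threshold;
only drastic shifts (≳ 25-fold, e.g. near-complete methylation gain or
loss in one pool) are detectable. This is consistent with hypervariable
regions being rare calls in practice, and it is why the synthetic
epiallele scenario plants a 25-fold pool-private shift.

Set overlap between two DMR lists counts ≥ 1-bp interval
intersections; the shared count is over intersecting pairs (symmetric
in argument order), the exclusive counts treat each DMR once.

## Annotation and phenotypes

Gene association is file-driven (gene table + optional pathway map; no
live database queries): a gene associates with a DMR when the
edge-to-edge gap is ≤ 10 kb (0 if overlapping), both directions,
strand-agnostic, listed nearest-first with symbol tie-breaks. Category
rollups count a DMR once per distinct category among its associated
genes; pathway rollups count unique gene symbols per pathway. The
functional categories are an input vocabulary — the original manual
curation cannot be reproduced algorithmically.

Behavioral classification uses the control lineage only: visual deficit
is a startle value strictly below the control 5th percentile,
hyperactivity a locomotion value strictly above the 95th (strict
inequalities because the criteria are stated as "less/greater than";
a value exactly at a bound is normal). Percentiles use linear
interpolation between order statistics, exposed as config since
software packages disagree at small n; pooled across sexes. The
outlier rule excludes fish moving < 25% of the recording time (strict;
0.25 exactly is kept); the 4-SD-below-mean criterion is computed and
flagged but secondary to the 25% rule, and an audit warning fires when
a lineage loses more than 2 fish. The joint-phenotype test compares
the observed number of fish abnormal in both assays with n·p₁·p₂ via a
1-df chi-square on the both/not-both split; lineages with degenerate
expectation (0 or n) are reported but not tested — the reason control
groups are excluded in practice. Percent change of an amplitude mean
from control rounds half away from zero to an integer, matching how
published amplitude tables round.

## Synthetic data

The generators define the study conditions; they are stand-ins, not
fits — no generative model for the real data exists.

* **Genome**: i.i.d. bases with every accidental CG broken, then CpG
  dinucleotides injected per 100-bp window at Poisson rates — the
  desert background (3/100 bp, matching the 2–4 CpG/100 bp regime
  reported for DMRs), dense clusters (12/100 bp in 5% of windows),
  and a repeat-rich arm tiled from a 72%-GC 25-mer on chromosome 4's
  right arm. Injection at even in-window offsets keeps the realized
  density exactly the planted rate up to Poisson noise and lets the
  CpG index be re-scanned from the final sequence. A Markov sequence
  model was deliberately not used: density statistics are all the
  pipeline consumes.
* **Counts**: window-resolution NB emission, mean = depth ×
  library-size factor × planted multiplier (fold change for
  exposed-group pools inside planted regions; hypo regions divide).
  The default study: 5 × 2 Mb chromosomes, 50 planted 3-window regions
  at 4-fold, depth 100/window, φ = 0.05, 3 pools per group with
  library factors 0.9–1.1. An optional read-level emitter writes
  50-bp BED reads whose midpoints realize the counts exactly
  (midpoints are placed strictly inside windows so the midpoint
  counting rule round-trips; exact only when window width exceeds
  half the read length, i.e. everywhere except sub-26-bp terminal
  windows).
* **Phenotypes**: both assays N(20, 5) in the control lineage,
  truncated at zero; exposure lineages shift locomotion up and startle
  down with ancestral dose (+4/−4 … +14/−14 over five lineages,
  n = 20 each, spanning partial to near-complete penetrance);
  fraction-of-time-moving N(0.6, 0.08) clipped to [0, 1], shared
  across lineages (the outlier filter is not modelled as a treatment
  effect).
* One global seed; every generator draws from a named substream
  derived via CRC32 of its label, so runs are reproducible and
  components are independently stable under fixed seed.

What passing on this emulation does **not** show: robustness to
GC/CpG-coupled coverage bias (counts are simulated independently of
the sequence), fragment-length effects (MeDIP fragments of 200–800 bp
are not modelled; an optional fixed read extension exists in the
counting path but defaults off), mapping artifacts in repeat regions,
or trended/tagwise dispersion. The published genome-wide DMR counts
from the original sperm libraries are not reproducible from this
package — they require the archived raw sequencing data and the
original differential-coverage software versions; the synthetic study
validates the procedure, not those numbers.

## Numerical and scale choices

The default study sizes (10 Mb genome, 10⁵ windows, 100 cluster-scan
null replicates, cohorts of 10³ for calibration checks) keep every
analysis script and the full test suite in the tens of seconds on one
core while leaving all Monte-Carlo bands narrow; they are the package's
declared desk-scale conditions. Degenerate inputs are handled
explicitly: zero-length chromosomes, all-zero libraries, off-chromosome
planted regions, unsorted window tables, empty DMR sets, and
no-replicate designs without a fixed φ all fail fast with messages;
zero-total windows and empty control lineages are the only silent
defaults (p = 1, and a hard error, respectively).
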