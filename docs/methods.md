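# Methods

## The measurement problem

A mycelial fungus growing down a tube extends linearly and apically in
cell-thick hyphae, so the number of cell divisions separating a sample
from the founding spore is simply the mycelium length divided by the
mean apical cell length, `D = L / (l × 10⁻⁶)` for `L` in meters and `l`
in µm. Sequencing the growing front at successive lengths and counting
the de novo mutations that rise to high frequency turns a mutation
-accumulation line into a per-cell-division rate measurement:
`μ = n / (G × D)` over `G` callable sites, and `μ / (l × 10⁻⁶)` per
meter of growth. This package implements that measurement end to end on
synthetic data with known ground truth: a forward simulator of the
growing front, a variant caller operating on per-position read-count
tables, trajectory/fate classification, and rate estimation with
confidence intervals and factorial comparisons.

## The growth and mutation model

The front is modelled as `n_tips` concurrently growing apical cells.
One division step extends every tip by one cell. During a step:

* each tip independently acquires `Poisson(μ × G)` new mutations, placed
  uniformly at unused positions (infinite sites — at ~10 mutations per
  tens of megabases, double hits are negligible);
* each tip branches with probability `branch_prob` (default 1.0, i.e.
  hyphal branching at essentially every division); each branching event
  lets the branch of one tip — chosen with probability proportional to
  fitness — overgrow and replace a uniformly chosen tip, keeping the
  front size constant. This is a Moran update with ~`n_tips` replacement
  events per division.

A mutation's true frequency is the fraction of tips carrying it, always
a multiple of `1/n_tips`. Under neutrality the classic Moran result
applies: new mutations fix at rate `μ × G` per division independent of
`n_tips`, with a fixation lag of roughly `n_tips − 1` divisions — the
linear accumulation that makes a single per-division rate meaningful.
Fitness costs are multiplicative, `(1 − s)` per protein-altering
(nonsynonymous, nonsense, frameshift) mutation, and act only on the
choice of which tip's branch overgrows.

Tube diameter is represented purely as the number of competing tips
(narrow default 4, thick default 20): a wider medium supports more
concurrent hyphae, and selection among them is more effective at larger
population size. No other tube-specific parameter differs except the
measured mean cell lengths (163 vs 165 µm) and the line lengths reached.

## Sequencing emulation

Samples are emulated at the level the caller consumes: per-position
counts of A/C/G/T and indel alleles. Depth at a site is
`Poisson(mean_coverage × m)` with a site multiplier `m`: callable
(mutation) sites are clean (`m = 1`), while background sites include 10%
repeat-like sites (`m ~ U(1.8, 3.0)`) and 10% dropout-like sites
(`m ~ U(0.05, 0.4)`). Real short-read coverage distributions have
exactly these tails (collapsed repeats, low-mappability regions), and
they are what make percentile coverage windows meaningful: the 10–90%
depth quantiles of the mixture bracket the clean bulk, so the window
excludes artifact-prone sites without clipping good ones. On a pure
Poisson depth distribution the same windows would discard ~20% of
perfectly good sites — an artifact of unrealistically narrow synthetic
coverage, not a property of the filter.

Each read reports the allele of a tip lineage drawn by frequency, then
is miscalled with total probability `seq_error` (default 1e-3), landing
uniformly on the three other bases. Indel-supporting reads are counted
as indel alleles; base plus indel counts always sum to depth exactly.
Double-sequenced sampling points (default: the first point of each
line) receive two independent read draws.

What the generator does **not** emulate: mapping and alignment (counts
are taken as given), base-quality information, error clustering or
strand bias, PCR duplicates, contamination, and real genome repeat
structure beyond the depth multipliers. Passing tests therefore
demonstrate that the calling/fate/rate machinery is correct and
calibrated for count-level data, not that any specific read-level
pipeline upstream is.

## Variant calling

Candidates are all (position, alternative allele) pairs with at least
one supporting read in at least one non-founder sample. Stage 1 keeps a
candidate if, in some sample, depth lies in the 10–90% window and the
allele frequency exceeds 30%, or depth lies in the 15–85% window and
the frequency exceeds 20% (frequency inequalities strict; windows
inclusive). Whether the published windows are depth quantiles or
fractions of mean depth cannot be decided from the text; quantiles are
the default (`coverage_window_mode="quantile"`), fractions of the mean
are available. Stage 2 keeps a candidate only if no founder read
supports it (`founder_max_support = 0`).

Two consequences worth knowing. First, at 135× and a 1e-3 error rate
the founder shows a spurious supporting read at ~4.4% of sites
(`1 − exp(−135 × e/3)`), so ~4–5% of genuine mutations are discarded by
the founder filter; the pipeline's rate estimates inherit a bias of the
same size (measured: −4.0% thick, −0.9% narrow), which is left
uncorrected because the filter is part of the measurement being
emulated. Second, the same arithmetic bounds the caller's recall of
mutations reaching 50% frequency at ≈95%.

Frequencies of surviving variants are assessed in every sample;
double-sequenced points take the arithmetic mean of the two replicate
frequencies, replicates with zero depth are dropped from the mean, and
a point with no usable replicate is reported missing (never 0).
Replicate averaging happens before fate thresholding.

## Fates and rates

Each called mutation's trajectory (frequency ordered by mycelium length)
is classified into a three-way partition: **fixed** if the frequency
reaches the fixation threshold (default 0.90, i.e. "all or nearly all
reads" with headroom for binomial noise at 135×) and stays there through
the last observed point; otherwise **reached-then-lost** if it ever
exceeded the reach threshold (default 0.70); otherwise **never
reached**. Trajectories ending above 0.70 without sustaining 0.90 are
still reached-then-lost but flagged `unresolved` for audit. Missing
points are skipped, never interpolated.

The mutation count entering rates is the number of called mutations at
or above the reach threshold at a line's final sampling point — the
accumulation-curve quantity, which at the thick-tube defaults has
expectation `μ × G × D ≈ 9.4` per line. A fixed-only count is available.
Group estimates are means of per-line rates (pooled-count mode
available; the two differ in the third significant figure). The default
interval is a two-sided Student-t on per-line rates; a BCa bootstrap
(`scipy.stats.bootstrap`) is the alternative. Factorial comparisons fit
`rate ~ C(founder) + C(tube)` by OLS with type-II sums of squares,
optionally adding final length and mean coverage as covariates.

## dN/dS

The counting approximation, not a codon-model likelihood: mutational
opportunity is tallied per CDS codon by enumerating all nine single-base
changes at equal rates (a change creating a stop counts as
nonsynonymous; stop-to-stop counts as synonymous), and
`dN/dS = (nN/sitesN)/(nS/sitesS)` with nonsense observations in the
numerator. The ratio is reported undefined when no synonymous mutations
or sites exist. On neutral simulations it is statistically
indistinguishable from 1; with `sel_coeff_nonsyn > 0` it drops, the
qualitative contrast of interest.

## Numerical and policy choices

* Sampling lengths map to division counts by rounding to the nearest
  integer; configurations whose sampling points collapse onto the same
  division are rejected, as are expected per-tip mutation loads above a
  configurable cap (default 1000).
* Coordinates are 0-based half-open internally; GFF3 and VCF emission
  converts once. Indels are descriptors `I:<seq>` / `D:<n>` anchored at
  the preceding base on VCF output.
* Seeding: one master seed per experiment; line *i* uses
  `SeedSequence((master, i))`, and within a line the demography, the
  site layout, and each sequencing library draw from separately spawned
  streams, so any stage reproduces in isolation and re-runs are
  byte-identical.
* Exactly constant growth-rate series return slope 0 with p = 1 (the F
  statistic is 0/0 there).
* Problem sizes in the test suite: unit and property tests run on small
  genomes (10⁴–10⁵ sites, hundreds of divisions); calibration checks run
  the full experimental geometry (G = 3.85×10⁷, 12,000 divisions,
  24 lines) over several master seeds, which resolves a 10% bias bound
  with ~2–3% Monte-Carlo error.

## Known limitations

* The callable-site denominator G = 3.85×10⁷ is the approximate
  reference genome size; the original measurement never printed its
  denominator, and rates scale inversely with it.
* Tip census per tube diameter is not observable in the source data;
  the 4-vs-20 defaults encode only "more competition in thicker tubes".
* No back-mutation, no multiple hits, no within-mycelium spatial
  structure beyond the front, no dikaryon genetics, no meiosis.
* The caller inherits whatever sits in the count tables: mapping
  artifacts upstream of counts are out of scope, and the mpileup
  adapter enforces no read-level filters.
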