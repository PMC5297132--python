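# Methods

## Model

`dimnp` treats differential nucleosome occupancy as a per-base test of
homogeneity. For *n* samples, at genomic base *k*, let *aᵢ* be sample *i*'s
normalized occupancy and *bᵢ* its background (the chromosome average of the
normalized track, identically 1 under global normalization). The 2×*n* table
with rows (*a*, *b*) and one column per sample is scored with the classical
homogeneity statistic using marginal expected values

    Aᵢ = (aᵢ + bᵢ) · Σⱼaⱼ / Σⱼ(aⱼ + bⱼ),   Bᵢ = (aᵢ + bᵢ) · Σⱼbⱼ / Σⱼ(aⱼ + bⱼ),
    χ² = Σᵢ [ (aᵢ − Aᵢ)²/Aᵢ + (bᵢ − Bᵢ)²/Bᵢ ],

with ν = n − 1 degrees of freedom — the (2−1)(n−1) of a 2×n table — and the
P-value is the upper chi-square tail, computed through the survival function
(regularized upper incomplete gamma), floored at 10⁻³⁰⁰ so −log₁₀P stays
finite. Under the null the *n* columns share one composition; a base where
one sample subset departs from the rest makes the columns heterogeneous in
exactly the way the statistic measures, whichever subset it is — this is
what lets a single pass replace all pairwise comparisons.

### The count scale, and why it is not optional

The statistic is scale-linear: χ²(c·a, c·b) = c·χ²(a, b). A mean-1
fold-change track with b ≡ 1 therefore caps χ² at order 1 for any realistic
contrast (a 3-fold gain in one of three samples gives χ² ≈ 0.7, P ≈ 0.7 at
ν = 2), and no base could ever cross a 10⁻⁵ cutoff — the caller would be
structurally unable to call. A chi-squared statistic is only calibrated when
its entries carry the sampling variance of counts. `call_chi2` therefore
multiplies both rows by a single scale factor, by default the pooled mean
raw coverage (the mean of the samples' per-chromosome `raw_mean`), so the
test sees depth-equalised read counts: the profiles stay mean-1 fold-change
tracks (depth differences cancel), and by scale linearity the statistic is
exactly χ²(fold change) × coverage. `scale=1.0` recovers the raw
fold-change behaviour for anyone who wants it.

The approximation is still applied to non-integer smoothed values, as the
method defines; the chi-square null is an approximation, not an exact
sampling distribution. The homogeneity-null simulations below measure how
conservative it is in practice: at n = 3 and 30 reads/nucleosome the suite's
null simulation bounds the fraction of testable bases with P < 0.01 at a few
percent, and the observed fraction sits far below the nominal 1% — strongly
conservative, because the background row is noise-free and the extension
step smooths counts.

## Occupancy estimation

Single-end reads are mapped to a 75-bp window anchored at the 5′ end,
shifted 37 bp toward 3′ (minus-strand arithmetic mirrored), clipped to the
chromosome; for ~147-bp nucleosomal fragments this places the window around
the dyad. Paired-end fragments are used as their mate span, unmodified.
Pileup is a coverage count; each chromosome is normalized independently.

* **Global correction** divides by the chromosome mean, making the track a
  mean-1 fold change and cancelling sequencing depth exactly
  (`normalize_global(c·raw) == normalize_global(raw)`).
* **Local correction** divides by the mean of a constant-width window
  (default 10 kb) centered on each base. The window *clamps* at chromosome
  ends — it slides inward keeping its full width rather than shrinking,
  reflecting, or zero-padding. Interior bases are identical to the centered
  definition; ends average only observed data; and a window at least as wide
  as the chromosome reduces *exactly* to global correction, which is the
  degenerate limit the test suite asserts at 10⁻⁹. A truncated (shrinking)
  window was rejected because its half-window at an end covers only half the
  chromosome, so the degenerate limit would fail by construction. Bases
  whose window mean is zero are flagged untestable and excluded from
  calling. Windows well below the nucleosome repeat length divide signal by
  itself and should not be used; the option exists for exploring
  chromosome-scale trends, and in the degenerate-window regime it matches
  global correction.

## Segmentation and FDR

Bases with P strictly below the cutoff (default 10⁻⁵) form candidate runs;
candidates shorter than 10 bp are dropped, then adjacent survivors with a
gap strictly below 5 bp are merged, in that order (the reverse order gives
different results; drop-then-merge is the definition here, and merging can
only lengthen regions so no re-filtering is needed). Both comparisons are
strict: length exactly 10 is kept, gap exactly 5 is not merged. Each
region's representative P is the per-base minimum inside it (the
peak-significance convention of region callers), its center the integer
midpoint, and FDR is Benjamini–Hochberg across the per-region representative
P-values (via `statsmodels`); BH is our choice of estimator, monotone in P
and order-invariant. "Gap" means next start minus previous end, not
center-to-center distance.

## Evaluation machinery

* **Manual ratio caller** (two samples): a base is flagged when
  (x+ε)/(y+ε) leaves [0.6, 1/0.6] (strict), with pseudocount ε = 0.01 in
  fold-change units guarding division by zero at unoccupied bases; flagged
  runs pass through the same drop/merge rules. The rule is antisymmetric in
  the sample order. Pairwise sets are pooled by interval union (touching
  intervals coalesce) to form a multi-sample reference.
* **ROC** is computed per base: truth label = inside/outside the reference
  intervals, score = −log₁₀P, over testable bases, with
  `sklearn.metrics.roc_curve`. A region-level "overlaps the reference" rule
  alone defines no false-positive *rate*, so it is reported separately as
  precision at each P cutoff. The trapezoidal AUC is checked against the
  Mann–Whitney U identity AUC = U/(n₁n₀) computed independently from
  midranks; the two agree to machine precision on any input.
* **Matching curves**: a query region is matched at deviation *d* bp when
  its center is within *d* of the nearest target center
  (center-to-center distance; curves are non-decreasing in *d* by
  construction, evaluated at 1..100 bp by default).

## Synthetic data generator

The generator emulates the structure the test assumes: a chromosome with a
regular nucleosome array (dyads every 165 bp — a typical yeast repeat
length), 147-bp protected fragments, per-nucleosome read counts
Poisson(reads_per_nucleosome × depth_factor × fold), Gaussian dyad jitter
(default σ = 20 bp, the positional spread of reasonably well-positioned
nucleosomes), and single-end 50-bp reads emitted from either fragment end
with matching strand — so the 75/37 extension-and-shift path is exercised
and approximately reconstructs the fragment body. Planted regions multiply
the Poisson mean by a chosen fold in a chosen sample subset and are emitted
as ground truth. Everything is driven by one `numpy` Generator seed;
BED output is byte-deterministic.

What it does **not** emulate: MNase digestion bias, GC bias, fuzzy or
delocalised nucleosomes, linker-length heterogeneity, mappability gaps, and
chromosome-scale coverage waves. Passing tests on this generator show the
pipeline's statistics, segmentation and bookkeeping are correct under the
model's own assumptions; they do not certify calibration on real chromatin,
where the chi-square approximation inherits all of the above.

### Study conditions and measured power

The default conditions used by the test suite and `scripts/acceptance.py`
are 3 samples, 200-kb chromosome, fifty 300-bp planted regions at fold 3
affecting one sample, 30 reads/nucleosome (≈ 13.6× mean base coverage after
extension), global normalization, cutoff 10⁻⁵. At this depth a fold-3 dyad
gives depth-equalised counts ≈ (84, 28, 28) against backgrounds ≈ 13.6,
i.e. χ² ≈ 9 at ν = 2 (P ≈ 0.01) — an order of magnitude short of the
χ² ≈ 23 that a 10⁻⁵ cutoff demands. Measured on these conditions:
**0 DNRs at 10⁻⁵ (sensitivity 0), per-base ROC AUC ≈ 0.85**, and the AUC
equals its Mann–Whitney formulation to < 10⁻⁶. Detection at 10⁻⁵ needs
either stronger contrast or more depth: at fold 8 and 60 reads/nucleosome
the same pipeline recovers all planted regions with sensitivity and
precision 1.0 (the README's worked example). This is a property of the
statistic at that coverage, not a bug; the numbers are reported as measured.
Null behaviour at the same depth is clean: zero DNRs under the homogeneity
null and under a 5-fold depth imbalance after global normalization.

Problem sizes throughout (50–200 kb chromosomes, ≤ 3 samples, 1000-table
oracle sweeps) were chosen as the smallest at which every quantity of
interest is measurable with stable Monte-Carlo error; the full acceptance
script runs in seconds.

## Numerical and degenerate-input choices

* P-values floored at 10⁻³⁰⁰; untestable bases (all-zero observation row,
  or zero local background in any sample) get P = 1 and `testable = False`,
  so they can never seed or extend a region and downstream code needs no
  NaN handling.
* Coordinates are 0-based half-open everywhere, BED/bedGraph conventions on
  disk; chromosome frames default to the maximum observed end and can be
  fixed with a chrom-sizes file (reads on unknown chromosomes are dropped
  with a logged count). When samples' observed frames differ at `call`
  time, shorter profiles are zero-padded and the padding marked untestable.
* Paired-end input: BED lines already spanning the fragment are used as-is;
  otherwise mates are joined on an identical name field; unpaired reads are
  dropped with a logged count, and forming zero pairs is an error
  (suggesting single-end mode).
* Empty inputs error early (empty read file, zero-coverage chromosome,
  empty reference for ROC, empty query for matching); an empty *result*
  (no DNRs) is not an error.
* Determinism: all randomness flows from explicit seeds; output files are
  written in sorted order with fixed float formats, and two identical CLI
  runs are byte-identical.

## Known limitations

* The chi-square approximation on smoothed per-base values is conservative
  rather than exactly calibrated; P-values are ranking scores more than
  frequentist error rates.
* Per-base testing ignores spatial correlation (a ~75-bp window of
  dependence from the extension step); the 10-bp minimum length is the only
  guard against correlated single-base flukes.
* The background row is noise-free by construction, which dampens the
  statistic relative to a two-condition count test; power at a given fold
  change grows linearly with coverage.
* No replicate-aware variance model: biological replicates of one condition
  should be merged or compared explicitly as samples.
* Local correction below ~2 kb windows suppresses genuine nucleosome signal
  (it divides the signal by itself) and inflates noise.
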