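# Methods

This note documents the models and procedures the package implements,
the defaults and why, and what the synthetic generators do and do not
emulate.

## Promoter windows

Windows span −`upstream`..+`downstream` around the annotated gene start
(defaults 100 and 50).  Position +1 is the first base of the gene and
there is no position 0, so the default window is exactly 150 nt.  For a
minus-strand gene the genomic slice `[end − downstream + 1, end +
upstream]` is reverse complemented so every window reads in gene sense.
On a circular genome windows wrap (equivalent to extraction on the
doubled sequence, which is how the property is tested); on a linear
contig they are clipped and flagged `truncated` rather than dropped, so
the search space is preserved but truncation stays auditable.
External coordinates are 1-based inclusive (GFF3 convention); all
internal arithmetic is 0-based half-open.  IUPAC ambiguity codes other
than N are rejected in strict mode (default) or mapped to N, because
the scanners need a concrete 4+N alphabet.

## Repeat-motif scanning

**Individual inverted repeats.**  All (k, left_start, spacer) with
k ∈ [kmin, kmax] = [6, 15] and spacer ∈ [0, k] where the right arm is
the reverse complement of the left arm.  Arms containing N never match
(conservative: masked sequence cannot inflate counts).  Two filters
follow:

* *low complexity*: the oligo must contain at least one C or G;
* *subsumption*: an IR is dropped when a retained IR of strictly larger
  k contains both of its arm intervals inside the corresponding longer
  arms.  "Better represented by a longer oligo" is deliberately
  formalized as two-sided arm containment applied from the longest k
  downward to a fixpoint — the only reading we found that is
  well-defined and order-independent for nested families.

**Overlapping pairs** are unordered pairs of distinct surviving IRs
whose footprints (left arm start through right arm end) intersect in at
least 1 bp.  No minimum overlap or phase constraint is imposed by
default; the classical (7-1-7)₂ operator structure satisfies the
≥ 1 bp rule.

**Tandem + inverted repeats** are three occurrences of an oligo at
p₁ < p₂ < p₃ with both gaps in [0, k] (occurrences may touch but not
overlap) and *exactly one terminal* occurrence reverse complemented —
configurations with the middle occurrence flipped, or both terminals,
are rejected.  Oligos equal to their own reverse complement are also
rejected: for a palindromic oligo every occurrence equals its reverse
complement, so the orientation rule is undecidable; this is a package
design choice applied identically in the scanner and the reference.

**Consensus scanning.**  A degenerate IUPAC pattern with a mismatch
budget is slid over both strands; a sequence N never matches any
pattern class.  Strict search means 0 mismatches, "relaxed" any larger
budget.  The three shipped Fur-box structural models (19-bp inverted
repeat, hexamer head-to-head-to-tail triplet, overlapping heptamer
(7-1-7)₂) carry *placeholder* generic patterns: the structures are
documented in the literature but no validated operator sequence exists
for this organism, so real searches should override the patterns from
configuration.

**Verification strategy.**  The production scanner builds k-mer
position indexes; `lumenstarve.reference` re-implements every stage as
a literal brute force over all position combinations.  The test suite
requires exact agreement of the full chain on hundreds of seeded
AT-rich random sequences, and the synthetic promoter generator accepts
a sequence only when the reference sees exactly the planted motifs.

## Expression analysis

The pipeline starts at a probe-level intensity table (probe × sample,
linear scale, each probe mapped to one gene).  Scanner-file parsing and
convolution background correction are out of scope — they belong to
vendor tooling and are replaceable by the table interface.

1. **Quantile normalization** forces every array onto the mean
   empirical distribution; ties receive the mean of the reference
   quantiles they span.  The operation is idempotent and
   scale-equivariant (a global intensity factor shifts all log2
   summaries by a constant and leaves folds and calls unchanged).
2. **Median polish** (Tukey) per gene block on log2 values: alternating
   row/column median sweeps until the reduction in total absolute
   residual drops below `tol` = 0.01 (or 10 sweeps).  The per-sample
   summary is overall + column effect; the decomposition identity
   `data = overall + row + column + residual` holds exactly.
3. **Testing**: pooled-variance two-sample t-test between treatments
   (the classical default of the era's array tools; Welch via config).
   Degenerate convention: zero variance in both groups gives p = 1 on
   equal means, p = 0 otherwise.  No multiple-testing correction by
   default, matching the two-threshold fold rule it accompanies.
4. **Calling**: a single gene needs max(fold, 1/fold) ≥ 2.0 and
   p ≤ 0.05.  An operon — a maximal run of consecutive same-strand
   genes with every intergenic gap ≤ 25 bp ("no or very small
   intergenic space") — is called when all members agree in direction,
   each has p ≤ 0.05, and the geometric-mean fold is ≥ 1.7 (folds are
   ratios, so "average fold" is geometric, i.e. arithmetic on log2).
   Genes inside a called operon are reported once, within the operon.

Quantile normalization is rank-based, so strongly *asymmetric*
differential expression (many genes moving in one direction) shifts
whole-array distributions and attenuates observed folds.  The planted
benchmarks therefore balance directions, as real light/dark responses
roughly do; this attenuation is a real property of the method worth
remembering when interpreting one-sided contrasts.

## Physiology estimators

* **ATP shifts.**  The light source toggles every 5.5 min and samples
  are taken 5 min into each period.  Each dark→light shift's percent
  gain is 100·(light − dark)/dark against the *immediately preceding*
  dark reading (configurable to the mean of flanking darks); the
  summary is mean ± sample s.d. (n−1) of the last `n_last` = 3 shifts.
  The statistic is a ratio, so it is invariant to ATP unit rescaling.
  The luciferase standard curve is an OLS line mapping ATP amount to
  luminescence, inverted for prediction.
* **Radiotracer uptake.**  The killed-control mean is subtracted per
  timepoint and the rate is the OLS slope of the corrected means versus
  time (DPM/min), with the regression standard error.  Per-timepoint
  subtraction (rather than slope differencing) is the default because
  it also removes any time-varying abiotic adsorption shared by both
  series.  The light/dark contrast is 100·(light − dark)/dark.  When
  summarizing Monte-Carlo replicates, rates are averaged before taking
  the contrast: slopes are unbiased, whereas a mean of per-run ratios
  inherits an upward bias of order CV² of the dark slope.
* **Respiration.**  For each interval between (sparse, 10–14 h)
  measurements: volumetric rate = −Δ[O₂]/Δt (µmol L⁻¹ h⁻¹, replicate
  bottles averaged); per-cell rate divides by the *geometric* mean of
  the bounding densities (cells grow between sparse measurements;
  arithmetic available via config), reported in amol cell⁻¹ h⁻¹.
  Both bases are reported because light/dark comparisons can be made on
  either.
* **Cell volume.**  Sphere (4/3)π(W/2)³ for starved rounded cells;
  spherocylinder π(W/2)²(L−W) + (4/3)π(W/2)³ for vibrioid cells.  The
  spherocylinder reduces exactly to the sphere at L = W.  A width of
  0.30 µm gives 0.0141 µm³, the scale of a fully starved cell.

## Synthetic data

All generators are pure functions of seed and parameters (byte-
identical reruns) and emit inputs that pass the consumer modules'
validation, alongside a JSON-serializable planted-truth registry.

* **Promoters**: i.i.d. background at GC 0.30 (AT-rich, like the
  organism); motifs are planted by solving the same/complement position
  constraints with a parity union-find and embedding the segment at a
  random offset.  A rejection screen re-scans each sequence with the
  brute-force reference and regenerates until exactly the planted
  motifs of the planted classes are present.
* **Expression**: per-gene baseline log2 ~ N(7, 1.5), per-probe offsets
  ~ N(0, 0.5), 8 probes/gene, triplicates per treatment, i.i.d. normal
  log2 noise with s.d. 0.25; planted effects add log2(fold) to one
  treatment.  Operon plants are laid out as consecutive genes with 5-bp
  gaps on a virtual chromosome (singletons 200 bp apart) so the operon
  grouper finds them.
* **ATP / uptake**: multiplicative lognormal noise (CV 0.05 for ATP;
  uptake noiseless by default) — positivity-preserving, as befits
  luminescence and count data.
* **Growth/O₂**: a deliberately minimal carbon-budget model —
  exponential growth at µ = 0.04 h⁻¹ from 5×10⁷ to a carbon-set ceiling
  of 4.7×10⁸ cells/mL (densities of the real experiments), each new
  cell costing a fixed O₂ increment; after carbon exhaustion the
  density is constant and O₂ falls at 3 amol cell⁻¹ h⁻¹ in the dark,
  suppressed by a fraction f in the light.  Growth trajectories are
  identical in both conditions by construction.  This is a test
  harness for the estimators, not a claim about SAR11 bioenergetics.

What the generators do *not* emulate: probe-sequence affinity,
spatial array artifacts, photocycle kinetics, diurnal entrainment,
carry-over between shift periods, or cell-size distributions.  Passing
tests therefore demonstrate correctness of the estimators under the
stated noise models, not robustness to every artifact of real data.

## Numerical and design choices

* Ordering of motif hits is fully deterministic ((left_start, k,
  spacer) for IRs; (p₁, k, p₂, p₃) for tandems), so reports are
  byte-stable.
* All pipeline randomness derives from one root seed through SHA-256
  named substreams (< 2³¹), one per stage.
* Fold thresholds, window sizes, k range, α, the 25-bp operon gap and
  the 3-shift summary are configuration with the study defaults baked
  in; the run manifest records the exact values used plus output
  digests.
* Problem sizes in the test and acceptance simulations (hundreds of
  sequences of length ≤ 300; 500–2000 genes; 200–300 Monte-Carlo
  replicates) were chosen as the smallest sizes at which the binomial
  acceptance bands and oracle sweeps are meaningful.

## Known limitations

* The subsumption filter's fixpoint is defined longest-first; other
  orderings of the ambiguous prose rule would retain slightly different
  nested families.
* Consensus Fur-box patterns are placeholders (structures, not
  validated sequences).
* The operon rule requires per-member p ≤ 0.05; an aggregate-level
  test is available via config but not default.
* Respiration rates assume well-mixed sealed bottles and ignore optode
  drift; uptake fitting assumes linearity over the sampled window
  (no saturation term).
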