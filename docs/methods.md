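# Methods

## The spike-in model

A sequin is a synthetic DNA standard derived from a source genome so that it
shares the genome's *statistical* features but none of its alignable
sequence. The derivation is: sample random windows of 1–10 kb, reverse the
character order of each window, screen the reversed candidates for residual
homology, and keep the candidate whose GC is closest to the source genome's
GC (or to an explicit per-genome target, which is how deliberately
extreme-GC standards are made).

**Why reversal and not reverse complementation.** Reversal preserves the
per-base composition exactly — the A/C/G/T counts, the GC fraction and the
multiset of homopolymer run lengths are invariant — while destroying
k-mer-level identity with the source. A reverse complement would also
preserve composition only up to A↔T/C↔G exchange, and, more importantly,
would remain perfectly alignable to the opposite strand of the source.
Reversal is an involution, which the test suite asserts on random strings.

**Homology screen.** The screen rejects any candidate sharing an exact
substring of length ≥ `min_match` (default 30 bp) with any source genome,
either strand, or with a previously accepted sequin. It is implemented by
k-mer seeding (k = 18) with maximal extension around each seed hit. The
background index stores every s-th k-mer with s = min_match − k + 1; any
shared substring of length ≥ k + s − 1 = min_match is then guaranteed to
contain an indexed seed, so the accept/reject decision is exact, and the
measured length of any detected match is exact (extension is maximal).
Shared substrings shorter than the seed threshold may be reported as 0;
they cannot affect the decision because min_match ≥ k. The unit tests
compare the screen against an O(n·m) dynamic-programming
longest-common-substring oracle on small instances with planted matches.
An external BLAST-style screen can be substituted by screening candidate
FASTA files outside the package; the built-in screen keeps the design fully
self-contained and deterministic.

**What the screen does not model:** E-value statistics, gapped or
mismatched local alignment. A 29 bp exact match with flanking near-identity
passes the default screen; for stricter rejection lower `min_match`.

## Mixtures

The quantification ladder (Mix A) assigns the n sequins to
`n_points` = 16 concentration points in twofold serial dilution:
point i has concentration anchor·dilution^(n_points−1−i), with the anchor
(60 attomoles/µL) defined as the *lowest* point. With 86 sequins the point
sizes are 6,6,6,6,6,6,5,…,5 — the remainder goes to the most concentrated
points, where estimates are best. Sequins are sorted by GC and dealt
round-robin across points so that every concentration point spans the GC
range; ties break lexicographically by id.

Mix B realises known fold changes as *concentration swaps*: a sequin at
point p exchanges concentrations with a sequin at point p + d, producing
one +d and one −d log₂ change per swap pair. Defaults: 25 pairs
(50 fold-change sequins), magnitudes {1, 2, 3} with 8/8/9 pairs, the
remaining 36 sequins equimolar. Consequences of the swap construction:

- Mix B is itself an exact 16-point ladder with the same point sizes;
- signs are balanced exactly (25 up, 25 down);
- expected log₂ fold changes are exact binary values, computed as
  log₂(c_B/c_A) on concentrations that are exact powers of two times the
  anchor;
- within each chosen point pair the two members are selected greedily to
  cancel the running total-mass imbalance Σ(c_hi−c_lo)(len_hi−len_lo), so
  the two mixtures carry (numerically almost) identical total DNA mass.
  Mass balance is what makes equimolar sequins read out as unchanged under
  plain total-count library-size normalization; without it every sequin
  would inherit a common offset of log₂(mass_A/mass_B). The residual
  imbalance with the default design is ~10⁻⁵ log₂ units, far below
  counting noise.

Swap-pair placement across the ladder prefers the points with the most
unassigned sequins (largest magnitudes placed first, since they have the
fewest feasible point pairs), with seeded tie-breaking; the whole
construction is deterministic given the seed. Because changes come in swap
pairs, `n_fold_change` must be even.

## Read simulation

`compose_sample` resolves expected *read-mass* weights: within the spike,
mass ∝ concentration × length (a molar concentration times a molecule
length is proportional to its DNA mass, and shotgun reads sample mass, not
molecules). Two spike modes mirror the two laboratory practices:
*fractional* rescales the spike to a fixed fraction f of total sample mass;
*fixed* adds a constant spike mass while community mass varies, so the
spike's read share falls as load rises — the basis of absolute
quantification.

Short reads: fragments of length ~Normal(350, 50) (clipped to the
reference), 2 × 125 bp pairs from the fragment ends on opposite strands.
Long reads: single-end, lognormal lengths with configurable mean
(default 2590 bp, shape 0.55). Per-base errors are drawn independently:
substitution, insertion, deletion at the model's rates; inside annotated
homopolymer runs (≥ 6 bp) the combined indel probability switches to
`homopolymer_indel_rate` (split evenly between insertion and deletion).
Preset models carry the published short-read (mismatch 0.127 %, indel
0.0077 %) and nanopore-class (mismatch 7.12 %, indel 8.71 %, homopolymer
indel 16.7 %) error-rate estimates as defaults, not claims. Base
qualities are constant (Phred 30 short / 10 long) because no analysis here
consumes them.

Every read carries a ground-truth placement (reference, 0-based half-open
interval, strand) and an edit log in read-oriented template coordinates;
the read sequence is reconstructable as `apply_edits(template, edits)`,
which the tests assert. `placements_only` mode draws the identical error
stream but skips sequence assembly, keeping multi-million-read ladder
experiments desk-scale; the placement stream is byte-identical between
modes for the same seed. `simulate_counts` goes one step further for
experiments that consume only the count matrix: independent Poisson counts
at the resolved weights.

The fixture-genome generator emulates finished microbial genomes only in
the features the design consumes: length scale (default 20–60 kb rather
than megabases, purely for tractability), GC spread (targets uniform in
0.20–0.71 via biased base sampling) and planted homopolymer runs (6–12 bp,
roughly one per 5 kb). It does not model repeats, coding structure,
k-mer composition bias, or inter-genome homology — so passing tests
demonstrate correctness of the machinery on communities whose members are
random sequence, not performance on real genomes with shared ancestry.
Real-data effects deliberately out of scope: PCR amplification bias
(libraries modeled are PCR-free; an optional quadratic GC-bias hook exists
but defaults off), adapter chimeras, duplicates, base-caller artefacts.

## Ladder analyses

- **Coverage**: mean depth = aligned bases / reference length; breadth =
  covered fraction from the union of intervals (computed by a global
  difference array; verified against per-base counting). SAM/BAM input
  uses primary alignments only.
- **Ladder fit**: OLS of log₂(mean depth) on log₂(concentration), sequins
  with zero coverage excluded and listed, never imputed. Slope SE from the
  standard OLS formula.
- **Detection**: a sequin is detected with ≥ 1 read. LoD = the smallest
  point concentration c such that detection is complete at every point
  with concentration ≥ c; dynamic range = top concentration / LoD. This
  operational convention makes full-point dropouts give dynamic ranges
  that are exact powers of the dilution factor; printed dynamic ranges are
  conventionally truncated (not rounded) to two significant figures, so a
  16-point twofold ladder reads "3.2 × 10⁴". If the top point itself has a
  dropout the LoD is undefined and the summary is flagged rather than
  guessed.
- **Bias profiles**: observed/expected = mean depth ÷ concentration,
  normalized to mean 1, sorted by GC or length. Dividing by concentration
  is what makes sequins spanning four orders of magnitude comparable.
- **Error rates**: per-base mismatch/insertion/deletion counts over aligned
  bases, stratified into homopolymer (≥ 6 bp runs) vs other reference
  context; edit positions are mapped back to reference coordinates through
  the placement strand. Welch's t-test (Satterthwaite df) compares
  per-reference homopolymer vs non-homopolymer indel rates; degenerate
  variance returns p = 1 with a warning instead of failing.
- **Saturation curves**: least-squares fit of the five-parameter logistic
  y = A + (D−A)/(1+exp(−B(x−C)))^E with A, D bounded in [0, 1] (the
  response is a fraction assembled or breadth), 20 seeded multi-starts;
  the exponent argument is clipped at ±50 to keep evaluation finite, which
  leaves the curve flat to ~10⁻²² in the tails. Non-convergence from all
  starts yields a flagged fit with infinite RSS.

## Differential abundance and normalization

Library-size normalization is total-count scaling (to the mean library
size). The differential test is Welch's t on log₂(normalized count + 0.5),
3+ replicates per group, with Benjamini–Hochberg adjustment across
features and α = 0.05 on adjusted p. This test is intentionally simple
and pluggable: the claims exercised here — sensitivity and specificity
against *designed* positive and negative controls — are properties of the
control framework, not of a particular count model, and a
dispersion-shrinking test would only raise power. The pseudo-count is 0.5;
CV uses the sample-SD (n−1) convention.

ROC orientation: smaller p = more positive; tied scores advance both axes
simultaneously; AUC by trapezoid (equals the tie-corrected Mann–Whitney
statistic, which the tests verify by brute-force pair counting). Positives
can be stratified by |expected LFC| against the full negative set.

Normalizations:

- *conventional*: per sample, (count/genome size) divided by the community
  sum of the same — fractions sum to 1 over community features. Exactly
  invariant to total load by construction.
- *absolute*: conventional fraction ÷ φ, with φ = sequin reads / total
  reads per sample. With a fixed-mass spike φ is inversely proportional to
  total DNA load (φ = m/(m+M)), so the rescaled index supports absolute
  between-sample comparisons.
- *RUV (control-based factor normalization)*: on the samples × controls
  matrix of centered control log-counts, take the first k left singular
  vectors W; regress each feature on [1, W] and subtract W·α. k = 0 is the
  identity; k must be < the number of controls. With k = 1 this removes
  any rank-1 sample effect exactly (to numerical tolerance) when the
  controls carry no biology — the designed equimolar set is exactly such a
  control. No claim is made of estimator-level equivalence with any
  specific published RUVg variant (centering and α-estimation details
  differ between implementations).
- *upper-quartile*: per-sample 75th percentile of nonzero counts, provided
  as a comparison baseline.

## Validation experiments and their scales

`metaquin.validation` fixes the default study conditions; the acceptance
script and the slow end of the test suite run these:

1. **Neat-ladder quantification**: 86 sequins designed from 86 fixture
   genomes, default ladder, error-free placements at the depth that gives
   the lowest point expected coverage 1.2× (≈ 10–14 M pairs depending on
   the realized design; chosen so every ladder point is measurable rather
   than by a fixed read budget).
2. **Mix A vs Mix B**: 3 replicate libraries each, Poisson count noise at
   the depth giving the lowest-mass sequin ≥ 50 expected reads per
   replicate — "high depth" operationalized at the ladder bottom, where
   the 3v3 Welch test is power-limited.
3. **Load experiment**: four ~100 kb community genomes, mass compositions
   A = (0.40, 0.30, 0.20, 0.10) and B reversed, totals doubling A1→A2→A3
   and B1→B2→B3, fixed spike = 5 % of the smallest total, 10⁶ reads per
   library; 60 species × sample-pair LFC comparisons under absolute vs
   conventional normalization.

## Numerical conventions and degenerate inputs

Coordinates are 0-based half-open throughout. Windows containing ambiguity
codes are discarded before inversion. Floats in the mixture CSV dialect are
written with shortest-round-trip `repr`, making write→parse→write
byte-identical. Design failures (no candidate passes the screen) are
reported per genome, not raised. Zero aligned bases, empty length lists,
single-class ROC input and zero community totals raise informative errors.
Every stochastic routine takes an explicit seed and is bit-reproducible
given it.

## Known limitations

- The screen's exactness threshold is `min_match`; sub-threshold homology
  is neither measured nor penalized.
- Fixture genomes are i.i.d. random sequence; design performance on real
  genomes with repeats and shared ancestry (more screen failures, fewer
  passing candidates) is not characterized here.
- The differential test assumes approximate log-normality of normalized
  counts; at very low counts its power is limited, which is why the
  validation calibrates depth at the ladder bottom.
- Long-read error injection treats bases independently; real nanopore
  error is context-correlated beyond the homopolymer stratification
  modeled here.
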