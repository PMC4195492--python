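# Methods

This note documents the models and procedures implemented in `genomesig`,
the parameter choices that matter, and the known limits of the synthetic
cohort the tests run on.

## Sequence handling

Assemblies are read as soft-masked FASTA with case preserved: lowercase =
repeat-masked (RepeatMasker / Tandem Repeats Finder convention), uppercase =
unique sequence. IUPAC codes other than N are mapped to N (keeping case) and
counted; they are rare in vertebrate assemblies and the analysis alphabet is
{A,C,G,T,N}. Coordinates are 0-based half-open throughout, so BED export
needs no conversion.

Fragmentation tiles each record independently from position 0 in
non-overlapping windows of one fixed length (default 100 kb). Trailing
short windows are discarded rather than padded: every frequency vector must
describe the same amount of sequence. A window whose N fraction strictly
exceeds 20% is dropped (a window at exactly 20% is kept — the filter reads
"exceeds"); retained windows normalize their counts to N-free windows, so N
content never dilutes a frequency. Fragmentation never crosses record
boundaries — scaffolds are not contiguous in reality.

The unique/repeat partition concatenates all uppercase runs (in genomic
order, across records) into one artificial record and all lowercase runs
into another, then fragments those. N/n residues follow their case.
Concatenation creates spurious junction k-mers at run boundaries; with
run lengths of 10²–10⁴ bp against 10⁵-bp windows this contributes < 1% of
windows and is ignored.

## Degenerate k-mer signatures

Only one strand is deposited in databases and the choice is arbitrary, so a
fragment and its reverse complement should produce the same vector. Each
k-mer is therefore pooled with its reverse complement into one class,
labelled `w+revcomp(w)` with w the lexicographically smaller member
(self-complementary words stand alone and are counted once per occurrence,
keeping Σ frequencies = 1). Class counts are 2/10/32/136 for k = 1/2/3/4.
Counting uses overlapping windows of step 1; windows containing N are
skipped and frequencies are divided by the number of N-free windows. Column
order is lexicographic in the canonical label, fixing vector layout across
runs.

## BLSOM

The batch-learning SOM differs from the online Kohonen SOM in both halves
of its loop:

* **Initialization.** Weights are laid out on a regular grid spanning ±2
  standard deviations along the first two principal components of the data
  (eigendecomposition of the covariance matrix; each component's sign fixed
  so its largest-magnitude loading is positive). The lattice has
  ~N/10 points (one per 10 fragments) and aspect ratio W/H = σ₁/σ₂, with
  W ≥ H ≥ 2. Negative components are clipped to 0 (frequencies are
  non-negative); weights are *not* renormalized to the simplex during
  training — they are prototypes, not frequencies.
* **Training.** Per epoch, every vector is assigned to its nearest weight
  (Euclidean; ties to the smallest linear index i·H+j), then every weight
  is replaced by the mean of the vectors assigned within Chebyshev radius
  r(t) = max(1, round(r₀(1 − t/epochs))) of it — a square neighborhood on
  the rectangular lattice, matching square-cell map rendering. Weights with
  empty neighborhoods keep their value. Defaults: 100 epochs,
  r₀ = max(W,H)/4, all configurable. The exact historical schedule for
  batch-SOM genome maps is not published in a reusable form; this linear
  decay with a pure neighborhood mean is simple, deterministic, and
  sufficient for territory formation.

Order independence is bit-exact, not just statistical: input vectors are
brought into a canonical lexicographic order before any floating-point
accumulation, so any permutation of the same multiset of vectors produces
identical weights. At the terminal radius of 1 the batch update can settle
into a tiny two-point limit cycle (~0.4% of the quantization error); the
guaranteed property is that final quantization error does not exceed the
initial error, and the last epochs are stable to well under 1%.

Purity is the fraction of fragments sitting on lattice points whose
fragments all share one species label; an optional label grouping (merging
near-indistinguishable species into one category) is applied before the
census and can only raise purity.

## Observed/expected diagnostics

Raw class frequencies track G+C% so strongly that a colored map mostly
re-draws the G+C% gradient. Each lattice point therefore gets an
observed/expected ratio: observed is the mean class frequency over the
fragments assigned there (weights are smoothed prototypes; occupied points
report their data), expected is Σ over member words of the product of the
lattice point's own mononucleotide frequencies. Empty lattice points fall
back to the weight vector for the observed value and to the weight's
mononucleotide marginal for the expected, and are flagged — grids have no
holes, but flagged cells are interpolations. Rasters map log₂(ratio)
clipped to [−1, 1] onto blue-white-red; the numeric TSV is the
authoritative output.

Territory contrast classifies a lattice point into a species partition when
the majority of its fragments belong to it, and reports fragment-weighted
mean ratios inside and outside.

## CG-suppression statistics

Genome-level levels pool raw counts over fragments (weighting by valid
windows) rather than averaging per-fragment ratios, avoiding
small-denominator noise; on pooled counts, fragmented and whole-assembly
analyses agree to the junction-window term. The normalized level of a word
set is Σ observed frequencies / Σ expected-from-mononucleotide frequencies.
Dinucleotide ratios (CpG/GpC, CA/AC, TG/GT) are single-strand frequency
ratios; CG is self-complementary so the headline CG statistic is
strand-proof either way.

The four deamination criteria are evaluated per genome: (i) pooled CG o/e
below 1, (ii) pooled TG and CA o/e above 1, (iii) Pearson r between
per-fragment CG o/e and G+C% positive, (iv) Pearson r between per-fragment
CG o/e and TG o/e — and CA o/e — negative. "Local" means per retained
fragment; at least 30 fragments are required. Level flags (i/ii) use a ±2%
margin around 1: a bias-free genome's pooled estimate is 1 ± sampling
noise, so a strict inequality would be a coin flip; the margin makes the
flags assertions of direction rather than noise. Correlation flags use the
sign of r, and r itself is reported so users can apply significance tests
downstream (Spearman is available as an option; the criteria name only
directions, not a statistic).

## CpG islands

A 100-bp window slides by 1 bp; a position is an island candidate when its
window has GC ≥ 50% and CG observed/expected ≥ 0.6 with expected =
C·G/window, and contains no N. Maximal candidate runs merge into intervals
spanning the union of their windows; intervals shorter than 200 bp are
dropped, and each surviving interval is re-checked against both thresholds
at the island level so every reported island is individually GC-rich and
unsuppressed (window merging alone does not quite guarantee this). This is
the classical sliding-window recipe; it is deliberately not bit-compatible
with any particular tool's refinement loop — the validated properties are
the threshold monotonicity and the inside/outside contrast. All five
parameters are exposed.

The inside/outside contrast computes the normalized CG level on the
concatenated islands and on their exact complement (every base pair counted
once); windows never span concatenation junctions.

## Synthetic genomes

The generator exists so that every stage can be tested against known truth
at desk scale instead of multi-gigabase downloads.

**Calibrated Markov chains.** A first-order chain with transition
p(b|a) ∝ π(b)·m(ab) is fitted by a double fixed point: π is multiplicatively
corrected until the stationary mononucleotide distribution matches the
target (A=T, C=G marginals from the target G+C%), and the effective
multipliers of the *requested* dinucleotides are corrected until their
realized o/e (computed analytically from the stationary distribution)
matches the request; both to 10⁻⁴ within 100 iterations, else an error
naming the offending multipliers. A first-order chain cannot hold all 16
o/e values at once — pinning the marginals while depressing CG forces
compensating excess in the rest of the C row and G column (CA, CC, CT, AG,
GG, TG rise ~1/(1 − π(G)(1−m))). The calibration therefore hits the
requested cells exactly and lets unconstrained cells absorb the
compensation; the realized matrix is returned for inspection. One visible
consequence: *every* strongly CG-suppressed preset shows elevated CC/GG
(and CCC+GGG ≈ the square of it), which in real genomes is an independent
signature dimension. Presets: coelacanth-like (G+C 0.43, CG o/e 0.31, CC/GG
1.15), medaka-like (0.405, 0.46), lamprey-like (0.46, 0.78),
marsupial-like (0.38, 0.13), isochore-bird-like (0.42, 0.25, isochore mode)
— G+C% values are realistic for the eponymous genomes; CG levels span the
observed vertebrate range.

Isochore mode resamples the target G+C per segment (default 1–5 Mb uniform,
±0.05 spread — the order of magnitude of long-range segmental G+C%
structure) and recalibrates the chain per segment. Repeat blocks (default
~10% of sequence in 0.5–5-kb blocks) are resampled from a chain with CC/GG
boosted ×1.3 on top of the host multipliers and written lowercase, so
unique/repeat separation is testable while repeats still carry their host's
CG signature. N runs are inserted at a per-bp start rate. Sampling is a
seeded numba loop over pre-drawn uniforms; everything is bit-reproducible
from (preset, seed).

**Deamination simulator.** Starting from any genome, each CG site per round
mutates with probability p·f(local G+C in a centered 1-kb window), becoming
TG or CA with equal probability — one CG lost is exactly one TG or CA
gained. With protection on, f ramps from 1 at ≤ 25% local G+C to 0 at
≥ 55%. The ramp must be steep: the CG→TG flux *relative to baseline TG*
grows with G+C% (CG sites scale with G+C² while TG scales with
(1−G+C)·G+C), so a shallow gradient such as f = 1−g produces a *positive*
CG–TG correlation and fails to reproduce the criterion-iv signature that
motivates the model. Applied to an isochore-structured base genome, the
protected simulator satisfies all four deamination criteria.

The no-compensation ablation replaces the C of a mutating CG by G, skipping
sites preceded by T. This is the only in-place substitution family that
creates strictly no TG and no CA: any replacement beginning with A creates
CA after a C neighbor, beginning with G creates TG after a T neighbor, and
mono-shifting replacements (e.g. CG→TA) lower π(G), which *raises* local
TG o/e through the expected term and keeps the CG–TG correlation negative
— masquerading as compensation. With the ablation, the CG–TG correlation
flips robustly positive (r ≈ +0.8) while genuine deamination gives
r ≈ −0.95, so criterion iv cleanly discriminates the mechanism.

**What the cohort does not emulate.** No gene/codon structure, no real
repeat families (LINE/SINE), no higher-order (k > 2) compositional bias
beyond what the first-order chain induces, no strand-asymmetric
replication effects, no CpG-island landscape in the Markov genomes (islands
are planted explicitly where needed). Passing tests therefore demonstrate
that the *estimators and the clustering* behave correctly on genomes whose
signature is known, not that any biological claim transfers to a particular
real assembly.

**Planted-island fixture.** The CpG-island tests use a 10-kb suppressed
background (G+C 0.30, CG o/e 0.2) with one 300-bp insert built from a
deterministic 100-bp tile (G+C 58%, exactly 7 CG per cyclic period), so
every window fully inside the insert passes both thresholds with margin and
the call cannot fragment on sampling noise. The A+T-rich background bounds
the call's overhang past the insert: a boundary window reaches GC ≥ 50%
only when > ~70% of it is insert, keeping the reciprocal overlap with the
planted interval above 80%.

## Problem sizes and numerical choices

The analysis drivers use 5 genomes × 10 Mb (500 fragments of 100 kb); the
end-to-end checks use 3 × 20 Mb for territory purity, 10 Mb per multiplier
for generator/estimator closure (sampling error of the CG level at 10 Mb is
~0.3%, well inside the ±0.02 closure band), and 5 Mb for the deamination
suite (50 fragments). These sizes put every statistic's sampling noise an
order of magnitude below the effects being measured. Ties in best-match
assignment break toward the smallest linear lattice index; PCA signs are
fixed by the largest-loading convention; chain calibration tolerance is
10⁻⁴ on both marginals and requested o/e; all seeds are explicit
parameters, and cohort child seeds derive from one master seed.

## Known limitations

* The BLSOM update schedule is one reasonable member of a family; absolute
  map geometry (not the clustering itself) depends on it.
* Requested multiplier sets that are jointly inconsistent (e.g. all 16
  cells constrained away from an achievable joint) fail calibration with an
  error rather than being approximated.
* Island detection aims at the classical recipe's behavior, not bit-parity
  with any specific implementation's island-refinement loop.
* Genome-level level estimates pool counts across fragments; per-fragment
  tables are provided, but no significance machinery is attached to the
  criteria flags beyond the documented margins.
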