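# Methods

## OSC potential

An off-frame stop codon (OSC) spans the junction of two consecutive in-frame
codons, read at offset +1 or +2. With a free neighbor on either side, a focal
codon c = c₁c₂c₃ participates in a completion whenever

* a stop s satisfies s₁s₂ = c₂c₃ (right neighbor, +1),
* s₁ = c₃ (right neighbor, +2),
* s₃ = c₁ (left neighbor, +1), or
* s₂s₃ = c₁c₂ (left neighbor, +2).

The potential *w(c)* counts distinct (stop, junction-offset) completions, not
distinct neighbors; under the standard stop set it ranges 0–6 (AGT attains 6)
and sums to 120 over the 64 codons (each stop matches 4+16+16+4 codon slots).
A historical aside: the figure that popularized this enumeration labels AGT
an arginine codon, though AGT encodes serine in the standard code; the count
is unaffected. Stop codons themselves receive a value in the table for
completeness but never enter the usage analysis.

## Transcript filtering

"Complete and unambiguous" is operationalized as: length divisible by 3, only
A/C/G/T, and no in-frame stop before the final codon. One terminal in-frame
stop is then stripped. The stripping is applied **before both** observed
counting and model training, so observed and expected counts are computed on
identical sequences and no constant offset enters L. Filtering is idempotent;
there is deliberately no minimum transcript length. Transcripts reduced to
zero length by stripping (a bare stop) are dropped.

## The 3-periodic Markov null

Order-k transitions P(b | context of k preceding bases, phase) with phase =
position mod 3, tallied per transcript with **no pseudocounts**: the training
text defines the support exactly, which is what makes the no-in-frame-stop
property of generated sequence exact for k = 2. Replicate transcripts are
seeded with the first k bases of their natural counterpart and extended to
the natural length, so transcript count and lengths are conserved exactly.

Contexts unseen at a phase can be reached only through natural-prefix
seeding. They back off to the longest observed suffix context (k−1, …, 1)
and finally to the phase-specific base frequencies; fallback draws are
counted and reported. The reference implementation the field used for such
generation does not document its fallback or RNG; both are this package's
own choices (numpy PCG64, one seeded generator per organism-run, seed
recorded in output metadata).

N = 200 replicates is the default; the replicate stream is shared across all
65 targets (pooled stops + 64 codons), which is statistically equivalent to
re-randomizing per target and ~65× cheaper. Within generation, replicates
are processed in memory-bounded blocks; the block schedule is deterministic
for fixed inputs, so a fixed seed reproduces counts exactly.

## Excess statistic

L = ln(O/Ē) with Ē the replicate mean. O = 0 yields a −∞ sentinel, Ē = 0
with O > 0 an undefined (NaN) flag; both are excluded from panel regressions
and counted. Significance: empirical one-sided rank p with add-one
correction, p = (1 + #{E ≥ O})/(N+1) for excesses (≤ for deficits);
the normal-approximation z-test p is emitted alongside for comparison only.
"% organisms with excess" counts raw L > 0. The 64 per-codon tests are not
multiplicity-corrected in the main columns (a Bonferroni column is emitted).
Panel GC regressions use GC as a **fraction** in [0,1]; the usage-panel
regression accepts `gc_units="percent"` where percent axes are preferred.

## Usage analysis

Per organism: Spearman ρ (average-rank ties, t-approximation p at n = 61) and
an OLS slope of relative usage on potential, over the 61 individual sense
codons. A grouped variant (7 potential-class mean usages) is available behind
a flag but is not the default — per-codon points are the only reading that
gives the correlation a meaningful sample size. The per-organism quantity
regressed on GC across a panel is the OLS slope; Spearman provides
significance classification only.

## Synthetic generator

The generator emulates exactly the structure the analyses assume and nothing
more: i.i.d. codons from a GC-driven law (independent bases at the target GC,
product over the codon, stops removed, renormalized), fixed or
geometric-over-minimum transcript lengths, optional terminal stops, and
optional dicodon-level injection — the proposal weight of the next codon is
multiplied by (1+δ) whenever appending it creates an off-frame occurrence of
the target at the junction (exact sequential reweighting, no rejection).

Two properties worth keeping in mind:

* **Realized GC ≠ gc_target.** Removing the AT-rich stop codons shifts the
  law's expected GC slightly upward (94/183 ≈ 0.514 at target 0.5). The
  target parameterizes the base law before stop exclusion; panel ordering in
  GC is unaffected.
* **What a green test establishes.** Synthetic organisms have no operon
  structure, no amino-acid-level selection, no realistic length distribution
  and no phylogenetic correlation between panel members. Calibration and
  recovery results therefore validate the *statistical machinery*, not any
  biological claim about real genomes.

## Order-≥2 nulls absorb dicodon stop injections (a power result)

For a single-stop target, the injected codon chain's induced base-level
conditionals depend on at most the two preceding bases: the reweighting
contexts for the +1 and +2 completions are disjoint because a stop's first
two bases differ. Consequently a trained 2–3 (or 5–3) model reproduces the
enriched off-frame rate *exactly*, and the excess statistic converges to
L = 0 — confirmed here both by exact stationary-chain computation and by the
full pipeline (measured |L| < 10⁻³ at δ = 0.5, versus ≈ 0.20 against an
order-1 null). Injection-recovery validation therefore runs against the
order-1 periodic null, the only order for which the question is well-posed;
conversely, this means the 2–3/5–3 machinery is structurally blind to
dicodon-level selection for (or against) off-frame stops, a caveat for
interpreting small excesses from such scans.

The expected L under any order of null is computed by an exact oracle:
stationary distribution of the injected 61-codon chain → stationary hexamer
law → aggregation to order-k periodic conditionals → stationary off-frame
rate of the aggregated chain. Edge effects (prefix seeding, finite transcript
length) are O(1/length) and ignored by the oracle.

## Defaults

| parameter | default | rationale |
|---|---|---|
| model order k | 2 (5 supported) | dinucleotide/pentanucleotide periodic models standard for CDS nulls |
| replicates N | 200 | replicate-mean stabilizes well before 200; configurable |
| alpha | 0.05 | conventional; empirical p floor is 1/(N+1) ≈ 0.005 |
| GC units (excess regressions) | fraction | slope magnitudes comparable across reports |
| synthetic panel | GC 0.3–0.7, 100–500 transcripts × 150–300 codons | bacterial-like GC span at desk-scale cost |
| seed schedule | per-organism seed = (master·1000003 + 7919·(i+1)) mod 2³¹−1 | reproducible piecewise, documented |

## Numerical notes & limitations

* The empirical test is slightly conservative: the null model is trained on
  the same data it is compared against, so replicate means track observed
  counts (posterior-predictive flavor). Calibration runs show mean L within
  sampling error of zero and false-positive rates at or below nominal.
* Spearman p-values use the t approximation (fine at n = 61); an exact
  permutation option would be needed for much smaller codes.
* Organisms are treated as independent; no phylogenetic correction is
  applied to panel regressions.
* Reverse-strand frames (−1/−2/−3) are out of scope; inputs are
  pre-extracted coding-strand CDS.
* Zero-variance degenerate inputs (uniform usage, constant GC) yield flagged
  results or errors rather than silent zeros.
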