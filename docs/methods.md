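# Methods

## Assay model

The pipeline analyzes the sequencing readout of an XNA replication-cycle
fidelity assay. A DNA template of defined sequence is transcribed into XNA
and reverse transcribed back into cDNA; the cDNA is PCR amplified, TOPO
cloned, and Sanger sequenced, one read per clone. The template layout is

```
[ 5' PBS (with AA watermark) ][ analysis region ][ 3' PBS (with TT watermark) ]
```

A clone that genuinely passed through the XNA intermediate carries the
*converted* watermark states (AA→TT in the 5′ PBS, TT→AA in the 3′ PBS),
because the converted bases are supplied by the extension and RT primers.
Carried-over template DNA retains the unconverted states and is excluded.
Because watermark and PBS bases are primer-dictated, fidelity is measured
only over the analysis region between the PBS spans.

The measured rates aggregate every enzymatic step of the cycle (XNA
transcription, reverse transcription, and PCR); no background correction is
applied. This matches how such scores are reported: they characterize the
replication cycle as run, not the XNA polymerase in isolation.

## Pipeline stages

1. **Orientation.** TOPO-TA inserts ligate in either direction, so each
   clone is aligned both as-is and reverse-complemented; the higher-scoring
   orientation is kept (ties → forward).
2. **Global alignment.** Needleman–Wunsch with Gotoh affine gap states,
   end-to-end: clones are full amplicons of a known template, so local
   alignment would only hide terminal errors. A gap of length k costs
   `gap_open + k·gap_extend`. Defaults: match +1, mismatch −2, gap_open 4,
   gap_extend 1 — chosen so that at the ≤~2% per-site error rates in play a
   true substitution is never re-explained as a compensating indel pair
   (one mismatch, −2, is cheaper than two single-base gaps, −10). All
   parameters are configurable. `N` aligned to anything scores 0 and is
   never a match, a mismatch, or an error. Traceback tie-breaking is fixed
   (diagonal > gap-in-clone > gap-in-template) so alignments are
   deterministic. The dynamic-programming kernel is numba-compiled; the
   unbanded exact algorithm is always used.
3. **Left-normalization.** Every gap run is shifted to its leftmost
   score-equivalent position (hops across equal bases of the non-gapped
   row), making indel coordinates in homopolymers reproducible. The
   operation preserves the score, the degapped sequences, and is idempotent.
4. **Identity filter.** Clones whose aligned identity falls below 0.7 are
   tallied as failed sequencing reads and excluded before the watermark
   check. The threshold is deliberately loose — real error loads are ≤~2%,
   so anything near it is junk — and explicit, since exclusions must be
   logged, not silent.
5. **Watermark filter.** A clone passes iff the bases aligned to both
   watermark dinucleotides equal the converted states exactly, with no gap
   at any of the four positions (a gap makes conversion unverifiable →
   fail). Each failure is classified (5′/3′/both unconverted, gap,
   low identity). Running a no-RT control dataset through the same filter
   yields a contamination pass-fraction.
6. **Mutation calling.** Only columns mapping into the analysis region are
   scanned. Mismatched base/base columns → substitutions; each maximal run
   of clone gaps → one deletion event of that length; each maximal run of
   template gaps → one insertion event anchored to the preceding template
   position. Columns where the clone reads N are skipped entirely — not an
   error, and not an opportunity.

## Statistics

Per substitution type, `μ(exp→obs) = #observed/#expected × 1000`, with
`#expected` the number of analyzed positions carrying the source base over
passing clones. Positions deleted in the clone or aligned to N are excluded
from `#expected` (a deleted position offers no substitution opportunity).
The total error rate sums the 12 per-type rates. A rate with zero
opportunities is reported as not estimable (`None`), never as 0.

The aggregate fidelity score divides the total error count — substitutions
plus every inserted and deleted base (a 2-nt deletion counts 2; nucleotide
incorporation events are the unit) — by the analyzed positions:
`(1 − errors/positions) × 100`, reported to one decimal with round-half-even
ties computed on the exact rational (immune to binary-float drift). The
denominator is analyzed positions, not positions + insertions; with indel
rates at the per-mille level the distinction is far below the reported
precision. Full precision is kept in the JSON report.

Note a consequence of per-opportunity denominators: on a base-balanced
template each source base supplies a quarter of the positions, so the total
error rate (sum of 12 per-opportunity rates) is ≈4× the per-position
substitution rate; it is **not** `1000 × (1 − fidelity/100)`. Both numbers
are reported separately; the aggregate score is the per-position quantity.

Per-type uncertainty uses exact Poisson (Garwood) intervals on the count,
scaled by 1000/#expected — appropriate for the small counts a few thousand
sequenced positions yield. Reports built from fewer than 1000 analyzed
positions carry a `low_coverage` flag, the assay's stated minimum depth.

## Synthetic data generator

The generator emulates exactly the statistical structure the pipeline
assumes:

- **Genuine clones** start as the watermark-converted template. Each
  analysis-region site is independently deleted with probability
  `del_rate`, otherwise its base is drawn from the 4×4 row-stochastic
  substitution matrix (so at most one of substitution/deletion per site,
  and P(substitution) = (1−del_rate)·(1−diagonal)); a single uniform-random
  base is inserted after the site with probability `ins_rate`. Watermark
  positions are exempt from the error model — in the assay they are primer
  synthesis products.
- **Contaminants** (template carryover surviving PCR) are exact template
  copies retaining the unconverted watermarks; `ceil(fraction·n)` of the
  dataset, default 0 since real contaminant frequency is not quantified.
- **Orientation**: each clone is reverse-complemented with probability
  `flip_fraction`.
- **Determinism**: every clone's stream is keyed by (seed, clone index), so
  a dataset prefix is stable under changes of `n` and identical parameters
  give byte-identical FASTA output.

Two-step error processes compose by matrix product
(`combined[a→b] = Σ_x first[a→x]·second[x→b]`) with indel survival
`1−(1−r1)(1−r2)`; a χ²-based test confirms one composed pass is
statistically indistinguishable from two sequential passes.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: sequence-context-dependent error spectra (real
polymerases are biased; the uniform model spreads errors evenly),
chromatogram quality and miscalls beyond isolated N bases, multi-base
indels, chimeric reads, and clone-to-clone coverage variation. Parameter
recovery on synthetic data validates the bookkeeping, not the biology.

The bundled design is a synthetic stand-in with the published structure
(20-nt PBS spans, 56-nt analysis region with 14 of each base, watermarks at
PBS positions 3–4); real designs are supplied via YAML.

## Problem sizes and numerical choices

The headline simulations use 10,000 clones × 56 analysis positions
(560,000 sites), which puts the standard error of the aggregate fidelity
score near 0.02 percentage points — an order below the one-decimal
reporting precision; each such run completes in a few seconds. Truth-table
comparisons use 1,000 clones; the alignment oracle check is exhaustive over
all sequence pairs of length ≤6 on a two-letter alphabet, with the
enumeration vectorized over all sequence pairs per gap pattern.

Known limitations: at indel rates ≫1% alignment ambiguity (homopolymer
placement, substitution+deletion pairs re-aligning as a single deletion)
makes individual event coordinates unreliable even though aggregate counts
stay accurate; the insertion anchor convention (preceding template
position) means an insertion before the first analysis base is attributed
to the PBS and not counted; deletions at the analysis-region boundary can
left-shift into the PBS if the boundary sits in a homopolymer.
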