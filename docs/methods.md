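# Methods

## Composition models

A genome's occurrence profile counts every overlapping n-mer on both
strands of every contig; windows containing a character outside
{A, C, G, T} are discarded and excluded from the total `M_i`. The NB model
stores add-one Laplace-smoothed log conditional probabilities
`ln[(f+1)/(M_i+N)]`, `N = 4^n`; all `N − k` unobserved n-mers share the
constant `ln[1/(M_i+N)]`, so models are held sparsely as sorted base-4
integer codes with parallel count/log-probability arrays. At the default
`n = 10` the space has ~1.05M dimensions while a 50 kb genome occupies
~10^5 of them. Profiles and models for `n` up to 15 are supported (codes
fit comfortably in 64-bit integers).

Fragment scoring sums `ln P(w|G)` over the fragment's valid n-mers, counted
on the given strand only: strand invariance comes from the both-strand
genome counts, so scoring the reverse complement of a fragment gives the
same ranking in expectation without doubling work. Likelihoods live in
natural-log space throughout; the product form is never evaluated because a
200-term product of n-mer probabilities underflows double precision. A
fragment with zero valid n-mers raises a distinct "unscorable" signal which
classifiers convert to a fully unclassified prediction.

## Classifier conventions

- E-value thresholds are strict (`E < threshold`); `E = 0.0` passes every
  threshold. Bit-score windows are inclusive at the boundary. Both choices
  fix otherwise ambiguous boundary behaviour deterministically.
- When a query has several hits to the same genome, the genome competes
  with its minimum E-value and maximum bit score; multiple local alignments
  per genome are common in real tabular output.
- All ties break lexicographically on genome id. Ties are measure-zero in
  float scores but certain in constructed tests, and reproducibility
  demands a total order.
- In NB-BL, genomes without a usable hit (`E < 10`) compete on their plain
  NB log-likelihood; when any hit has `E = 0.0` the decision short-circuits
  to the best NB log-likelihood among zero-E genomes, so `ln 0` is never
  evaluated.
- The ε-interval is inclusive (`logL ≥ logL_max − ln ε`), hence ε = 1
  reduces to the argmax and the ε-NB prediction coincides with NB wherever
  the maximum is unique.
- Consensus hybrids take the longest common label prefix of the two input
  predictions; a rank where either input is unclassified terminates the
  prefix. The operation is commutative, associative and idempotent, and
  never deepens either input.

## Taxonomy

A fixed eight-rank schema (domain, phylum, class, order, family, genus,
species, strain); labels are opaque, case-sensitive strings compared
exactly. Loading enforces rank-complete lineages and the tree property
(one label may not recur under two parents), so a label at a rank
identifies its clade unambiguously and LTR reduces to longest common
prefix. When a dataset has no separate strain naming, the strain label is
the genome id.

## Leave-one-out evaluation

`apply_exclusion` removes every genome under the excluded lineage prefix
from the training set and drops any query whose lineage at the excluded
rank is the only child of its parent — with no sister clade, a
parent-level assignment is vacuous. The evaluation loop enumerates every
sister-bearing lineage at a rank and pools confusion tallies before
averaging.

Per-lineage rates with zero denominators (Sp when `TP+FP = 0`; Sn/FNr/Ur
when `Z = 0`) are undefined and skipped by the averages rather than imputed
as zero, which would bias them. Averages weight lineages equally; absolute
(pooled) rates weight fragments equally. Both are reported because lineage
representation is rarely balanced.

For the correctness categories, `r` is the deepest rank the fragment's true
lineage shares with any *post-exclusion* training genome. Agreement is
checked from domain down to `r` only: an assignment deeper than `r` that is
still inside the rank-`r` clade is "correct lineage" (over-specific); the
four categories are exhaustive, so a prediction matching the truth only
above `r` counts as unclassified at `r`.

## Synthetic data

The generator's defaults are the package's study conditions: one domain,
3 phyla, one class and order per phylum, 2 families per order, 2 genera
per family, 3 species per genus, one strain per species (36 genomes),
single-contig genomes of 50 kb, and 100 fragments per species with contig
choice proportional to length when a full-size test set is requested.

Genome sequences follow a GC-calibrated order-2 Markov chain. Each clade
carries a GC fraction, AT/GC strand skews, and a 16×4 matrix of signature
logits that modulate emission probabilities per dinucleotide context;
children perturb their parent's parameters with per-rank standard
deviations that shrink toward the leaves (GC: 0.08 at phylum down to 0.004
at strain; logits: 0.40 down to 0.02). The signature gives each clade an
oligonucleotide dialect beyond raw GC — the genome-level compositional
structure that k-mer classifiers exploit in real data — while the GC knob
is bisected so the chain's stationary GC matches the clade's target within
1e-4. What the generator does *not* emulate: repeats, horizontally
transferred segments, coding/non-coding mosaic structure, and genome-size
variation; passing tests therefore demonstrate the classifiers' contracts
and relative behaviour, not absolute accuracy on real genomes.

Substitution noise changes exactly `round(pct/100 × L)` distinct positions,
each to a uniformly chosen different base (1% of 200 nt = exactly 2).
For a fixed seed the substitution sets are nested in the noise level, so a
noise series from one seed is coupled — the noise-degradation test uses
this common-random-numbers design.

Homology evidence is emulated rather than computed by BLAST. For each
(fragment, reference) pair at taxonomic distance `d` (0 = same genome, 8 =
different domain) a hit is emitted with probability decaying in `d`;
percent identity and alignment fraction are Gaussian around means that
decay in `d`; the bit score is a +1.2/−2.0 match/mismatch scoring of the
implied alignment and the E-value the usual `q·D·2^(−bits)` decay (with the
underflow printed as `0.0`, as BLAST does). The source genome's own hit is
a deterministic full-length perfect match, and all other identities are
capped below 1.0, so the source hit is never beaten when the source is in
the reference set. Fragment sampling weights contigs by the number of
eligible start positions `L − ℓ + 1` rather than raw length; the two are
indistinguishable for contigs much longer than the fragment and the former
leaves too-short contigs well-defined (weight 0).

All stochastic operations take explicit integer seeds; there is no global
random state, and every artifact (FASTA, TSV, hit tables) is byte-identical
across reruns of the same configuration.

## Problem sizes used in the test suite

The shared test world is the 36-genome default above. The monotonicity
suite uses 500 fragments of 200 nt; the recovery checks use ~100–200
fragments of 1000 nt (strain self-recovery) and 400 nt (exclusion runs
pooled over several excluded species); the noise suite uses 10 worlds ×
108 fragments of 200 nt at six noise levels. The acceptance script's
benchmark excludes one genus and classifies 100 fragments of 400 nt, per
its stated setup.

## Known limitations

- The NN classifier materialises dense `4^n` frequency vectors and is
  limited to `n ≤ 8`; it is intended for its default `n = 4`.
- The taxonomy model has no notion of intermediate ranks (suborder etc.)
  or name synonymy; inputs must be rank-complete.
- The hit emulator's E-values are calibrated for plausibility and
  monotonicity, not for agreement with any particular BLAST version's
  statistics; classifiers consume them only through thresholds and
  rankings.
- ε-NB's behaviour depends on fragment length: on long (≥1 kb) fragments
  log-likelihood gaps between genomes usually exceed `ln ε` at the default
  ε, and ε-NB then coincides with NB; its conservatism shows on short
  fragments.
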