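# Methods

Algorithmic conventions used by hgscan, in pipeline order. All randomness is
driven by explicit integer seeds through `numpy.random.default_rng`.

## Synthetic reference families

Each family starts from a seeded ancestor protein of fixed length; members
are drawn by substituting a fixed fraction of positions (default 10%),
keeping declared conserved positions and motif realizations intact. Motifs
are embedded at fixed 1-based reference columns: the hgcA cap-helix pattern
`N[VI]WCA[AG]GK` at column 90 (so the anchored Cys sits at column 93) and
the hgcB ferredoxin pattern `CxxCxxCxxxC` at columns 60 and 75. Defaults:
hgcA 145 members × 349 aa, hgcB 128 × 99 aa, recA 60 × 350 aa, plus an
unrelated 80 × 330 aa decoy family used only for specificity testing.

Benchmark communities place back-translated (uniform codon choice, table 11)
family members at fixed coordinates on random genomes. The two-genome
recovery community has a "carrier" (recA + hgcB + hgcA, relative abundance =
the target ratio) and a "host" (recA only), so the abundance-weighted
hgcA:recA copy ratio equals the target by construction.

The read simulator draws genomes proportional to abundance × length, insert
lengths from a rounded normal (mean 350, sd 30) truncated to
[insert floor, genome length], and 2×250 bp mates with independent per-base
errors (default 1e-3) and a two-state quality model (good/bad reads).

## Read preprocessing

1. **Adapter trimming**: the 3′ adapter is located by scanning for the
   best adapter-prefix match (≤10% mismatches, minimum overlap of 6 bp at
   the read end) and the read is cut there.
2. **Overlap merging**: mates are merged at the offset maximizing
   `overlap − 2·mismatches`, requiring a minimum overlap (default 10 bp) and
   at most `int(0.1·overlap)` mismatches. Consensus per conflicting base:
   higher quality wins with quality `|Q1−Q2|`; equal qualities give `N` with
   quality 0; agreeing bases keep the max quality. Swapping mates yields the
   reverse complement of the same consensus.
3. **Quality filter**: merged reads must reach a minimum length (default
   300 bp in the pipeline QC; fragments above `2·250 − min_overlap` cannot
   merge) and minimum mean quality.

## ORF calling

Six-frame scan under translation table 11 with start codons ATG/GTG/TTG
(alternative starts translate to Met). Strict mode requires start and stop;
partial mode (used on merged short-read fragments) also emits edge-truncated
ORFs without start and/or stop. `N` translates to `X`. Minimum length 30 aa
in the pipeline. Coordinates are 1-based on the forward strand for both
strands.

## Profile search

A from-scratch profile model per family, built from the ungapped member
alignment:

* **Match columns**: alignment columns with gap fraction ≤ 0.5.
* **Emissions**: `(count + pc·bg) / (n_nongap + pc)` with pseudocount weight
  1; background = pooled residue frequencies with one pseudo-observation per
  residue. Scores are log₂-odds; `X` scores 0 (neutral).
* **Alignment**: local Viterbi with affine gaps (open ≈ −4.17 bits, extend
  ≈ −1.17 bits, from transition probabilities p(M→I) = p(M→D) = 0.05,
  p(I→I) = p(D→D) = 0.4). The DP is banded around the candidate diagonal
  (±16) and stored band-relative for speed; a 6-mer seed prefilter (≥2
  shared 6-mers) selects candidates and the modal seed diagonal.
* **E-values**: Gumbel location/scale fitted (maximum likelihood) to scores
  of 1000 seeded i.i.d.-background sequences of the reference median length;
  `E = n_targets · exp(−(S−μ)/β)`. Uncalibrated profiles refuse to produce
  E-values. Reporting cutoff: E ≤ 1e-5.

An independent cross-check against pyhmmer (a different model family and
implementation) is part of the test suite: both must agree on
member-vs-random classification.

## Hit validation

* **hgcA**: the query residue aligned to reference column 93 must be Cys and
  the surrounding 8-residue window must match the cap-helix pattern on the
  read. Fragments whose alignment does not reach the motif, or whose motif
  window is cut by the fragment edge, are rejected with explicit reasons.
* **hgcB**: at least two non-overlapping ferredoxin motifs on the query.
* Length/gap plausibility rules (hgcA ≥ 175 aa, hgcB ≥ 50 aa, gap fraction
  ≤ 0.5) apply to assembled/full-length sequences before phylogenetic
  placement, not to read-level counting.
* Lineage labels come from the nearest reference member by global pairwise
  identity (ties to the lexicographically smallest member id).

## Quantification

Validated hits aligning ≥ 30 aa are counted per sequenced fragment: all ORFs
of a fragment collapse to the single best hit by (E-value, −bitscore,
family id), across families. Marker abundance is `100 · n_family / n_recA`
(percent of cells carrying the marker, via single-copy normalization); a
zero recA count makes the ratio *undefined*, never zero.

**Recovery oracle.** For simulated communities the expected counted-fragment
rate per family is computed exactly: for every retained insert length
(discretized truncated-normal weights over the merge/QC window) and every
fragment start, the fragment is detectable iff it contains ≥ 30 complete
in-frame codons of the gene and fully covers each required motif span.
Sequencing errors enter through a first-order motif-survival factor
(mate-overlap bases: consensus `N` at rate ≈ 2e; single-covered bases:
≈ 3/4·e non-synonymous). Quality dropout is position-independent and cancels
in recA-relative ratios, which is what the recovery tests compare.

## Module completion ratio

A module is an ordered list of components, each a set of alternative KO ids;
a component is satisfied when any alternative has a nonzero count. MCR =
100 × satisfied/components, rounded half-up to an integer. Missing KOs are
errors, not zeros. The packaged fixture holds the 10-KO reductive
acetyl-CoA (Wood–Ljungdahl) pathway counts for 19 station/depth samples.
Module abundance normalizes summed KO counts by ribosomal-protein totals;
profiles standardize row-wise to mean 0 / population SD 1.

## Mercury statistics

Mass concentrations (pg/L) convert to pM via the Hg molar mass
200.59 g/mol. "ND" (below detection limit) censors to 0 by convention.
Spearman correlation uses mid-ranks; two-sided p-values come from the exact
permutation null (all n! orderings) for n < 10 and the t approximation with
n−2 df otherwise. Constant inputs are reported as undefined rather than
given an arbitrary rho. The correlation table crosses marker families ×
{THg, MeHg, MeHg/THg} × {all samples, deep subset}; the deep subset is
depth ≥ 200 m by default or an explicit station list.
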