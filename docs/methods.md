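# Methods

This note records the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic data does and does
not emulate, and the numerical conventions that make runs reproducible.

## Coordinates and gene classification

All internal coordinates are 0-based half-open, the native convention of
refGene tables and BED; 1-based coordinates appear nowhere outside display
strings. A transcript's TSS is its span start on the plus strand and its
span end (one past the last transcribed base) on the minus strand.

Transcripts are collapsed per (chromosome, strand) into clusters by
transitive merging of overlapping *or abutting* spans. Abutting spans merge
because under the half-open convention no intergenic base separates them.
The cluster TSS is the 5′-most member TSS: this maximises the intergenic
promoter and is the common convention when a gene has several annotated
starts. The cluster's gene symbol comes from the member whose TSS equals
the cluster TSS (ties broken by lexicographically smallest accession), and
its evidence class is the best among members, ranked
curated-mRNA > curated-noncoding > predicted > other. Accession prefixes
outside NM/NR/XM/XR are retained with class "other" so non-RefSeq fixtures
pass through; predicted models (XM/XR) are excluded by every evidence
filter mode because they lack conclusive transcription evidence.

A bidirectional pair requires two TSS-adjacent clusters (no third TSS
strictly between) on opposite strands in divergent orientation with TSS
distance 0 ≤ d < 1000 bp; the upper bound is strict. Divergent pairs whose
gene bodies overlap are accepted as long as the TSSs are ordered
divergently; a negative distance (convergent geometry) is not.

The uni-directional definition is a conjunction: no opposite-strand TSS
within 10 kb upstream *and* no same-strand TSS within 1 kb upstream. The
two clauses could also be read disjunctively, but only the conjunction
guarantees that the full 1 kb of 5′ flanking DNA is an unshared promoter,
which is the point of the class. One boundary convention is deliberate: an
opposite-strand TSS at distance exactly 0 (a coincident head-to-head pair)
counts as "within the window". Otherwise a distance-0 pair member would
simultaneously qualify as uni-directional, breaking the invariant that the
pair set and the uni-directional set are disjoint at gene level. Distance 0
cannot occur for the same-strand test after collapsing, so its window is
0 < d ≤ 1 kb.

Redundant pairs sharing an identical intergenic interval keep exactly one
representative — the lexicographically smallest (plus symbol, minus symbol)
— so repeated transcript entries of the same locus pair do not inflate
counts.

## Promoter extraction

The bidirectional promoter is the entire intergenic interval between the
two TSSs. When shorter than the minimum CpG-island length (default 1 kb) it
can be extended symmetrically to that length; odd deficits put the extra
base on the left (arbitrary but fixed for determinism). Extension clamps at
chromosome bounds, shifting the shortfall to the other side when possible.
"Pure intergenic" mode skips extension so composition statistics reflect
only the sequence between the TSSs. The uni-directional promoter is the
fixed 1 kb upstream of the TSS, truncated (and flagged) at chromosome ends.

All promoter sequences are stored as forward-strand genome text. GC% and
CpG Obs/Exp are invariant under reverse complement (CpG is its own reverse
complement), and motif scanning covers both strands explicitly, so no
statistic depends on this choice. Extension may run into neighbouring gene
bodies; no avoidance is attempted because the promoter definition is purely
coordinate-based.

## CpG islands

GC content is (#C + #G)/(#A + #C + #G + #T). CpG Obs/Exp follows
Gardiner-Garden: (#CpG × L)/(#C × #G), with L the number of unambiguous
bases. N bases are excluded from all counts and break the CpG dinucleotide
(an N between C and G is not a CpG). Degenerate inputs are pinned: an
all-N sequence has GC 0 (with a warning) and a sequence without C or G has
Obs/Exp 0 rather than a division error.

The island finder (1) marks every window of length ≥ min_length that meets
both thresholds, (2) merges overlapping or abutting marked windows into
candidates, (3) verifies each candidate as a whole, trimming 1 bp at a time
from whichever end most improves the currently failing statistic (GC takes
precedence when both fail; ties trim the left end) until the candidate
qualifies or drops below min_length, and (4) reports the surviving disjoint
regions left to right. Step 1 considers windows of *every* length
≥ min_length, not only exactly min_length: a region can satisfy both
thresholds as a whole while no exact-length sub-window does (e.g. high-GC
content at both ends of a shallow dip), and including longer windows makes
the reported coverage equal, by construction, to the union of all
qualifying windows — the natural set-level definition of "island-covered".
Window statistics are computed from integer prefix sums and are bit-identical
to direct per-window counting; the test suite verifies agreement with an
exhaustive O(L²) oracle.

Two presets are provided: `gardiner_garden` (GC ≥ 0.50, Obs/Exp ≥ 0.60,
≥ 500 bp) and `strict` (GC ≥ 0.55, otherwise identical). Because the
"density" of islands per promoter class admits more than one reading, the
class summary reports both islands per promoter and islands per kb, plus
the fraction of promoters carrying ≥ 1 island and mean GC; empty classes
report undefined (None) fractions rather than 0.

## Functional enrichment and pair similarity

Term enrichment uses the upper-tail hypergeometric probability
P(X ≥ k | N, K, n) with population size N, K term carriers, study size n
and k observed carriers, evaluated via scipy's stable survival function.
Annotations are propagated through is_a ancestors first (the true-path
rule), as GO enrichment tools conventionally do. Multiple testing uses
Benjamini–Yekutieli (BH scaled by the harmonic sum c(m), valid under the
arbitrary dependence created by propagation), applied within each namespace
separately; gene-set (GMT) enrichment uses the one-sided Fisher's exact
test — identical to the hypergeometric tail on the same margins — with
plain Benjamini–Hochberg across the collection. Both adjustments are
selectable.

Within-pair similarity intersects the two members' *direct* term sets.
Propagated sets would make every annotated pair share the namespace roots,
collapsing the shared-count distribution to a constant; an exploratory
propagated mode exists and excludes terms of depth < 2 for that reason.
Unannotated members contribute empty sets and are flagged, not dropped, so
the denominator of the "fraction of pairs sharing ≥ 1 term" stays the full
pair count. The default population for enrichment is the set of clustered
genes that survived the evidence filter.

## Motif scanning and fold enrichment

Counts convert to log₂-odds with a pseudocount split by background:
score(b, j) = log₂((count(b,j) + pc·bg(b)) / (colsum(j) + pc) / bg(b)),
with uniform background and pc = 0.8 by default (a common smoothing
default; both are configurable). The hit threshold is
min + 0.8 · (max − min) of the achievable score range — the published
pipeline's scanner threshold is not recoverable, so this widely used
fraction-of-range rule is pinned and configurable. Windows containing N
never hit. Both strands are scanned; minus-strand hits are reported at
forward coordinates. Window scores accumulate column-by-column in the same
left-to-right IEEE order as a naive per-offset scorer, so results are
bit-identical to the brute-force reference.

Normalisation is hits per kb of total promoter sequence per class; per-kb
removes the length asymmetry between variable-length bidirectional
promoters and fixed 1 kb uni-directional promoters, which is exactly the
asymmetry normalisation must fix (a per-promoter alternative is available).
All overlapping occurrences count; no greedy non-overlap filtering.
Fold = bidirectional rate / uni-directional rate, classified at the 2-fold
threshold with inclusive boundaries (fold exactly 2.0 is over-represented,
exactly 0.5 under-represented). A motif absent from both classes reports
fold NaN and category "shared" with a both-zero flag so tables keep one row
per motif; a motif present only in bidirectional promoters reports fold ∞.
When two matrix collections are supplied, the over-represented sets are
intersected by motif name, case-insensitively.

## Synthetic data

The generator emulates the statistical structure the pipeline is built to
detect, at a scale where the whole analysis runs in seconds:

* **Layout** — default 2 chromosomes × 500 kb and 60 genes, half placed as
  head-to-head pairs (TSS gaps uniform in 100–900 bp, inside the < 1 kb
  pairing rule) and half as isolated genes, with ≥ 12 kb between units so
  planted uni-directional genes satisfy the 10 kb isolation rule exactly.
  Gene bodies are 2–4 kb. All planted features are recorded in a manifest.
* **Composition** — sequence comes from a first-order (dinucleotide) Markov
  sampler whose stationary base distribution pins GC exactly and whose C→G
  transition is scaled so the expected CpG Obs/Exp equals the target; an
  i.i.d. base sampler cannot decouple the two. Defaults: background GC 0.40
  / Obs/Exp 0.5 (CpG-depleted, genome-like), bidirectional promoters GC
  0.60 / Obs/Exp 0.9 (island-like), uni-directional promoters GC 0.45 /
  Obs/Exp 0.3. These contrasts reproduce the qualitative pattern that
  bidirectional promoters are CpG-island-rich and GC-rich.
* **Motifs** — three width-10 matrices with GC-balanced consensus strings
  (17/20 counts on the consensus base). Consensus copies are planted by a
  Poisson process into the extension-adjusted promoter intervals at
  class-dependent per-kb rates: SYNM_A 7.5 vs 1.5 (5× enriched in
  bidirectional), SYNM_B 5.0 vs 5.0 (equal), SYNM_C 1.5 vs 7.5 (mirrored).
  The absolute rates are set high enough that Poisson noise on ~15 kb of
  bidirectional promoter sequence cannot plausibly push the equal-rate
  motif across the 2-fold boundary or the 5× motif below it. Insertions
  overwrite background bases (no indels) so manifest coordinates are exact,
  and insertions of different motifs never overlap within a region.
* **Ontology** — three namespaces of 40 terms in a 4-level DAG; genes get
  2–4 direct terms from the depth ≥ 2 pool. Each pair shares ≥ 1 direct
  term with probability p_share (default 0.5, independently per pair) and
  is guaranteed disjoint otherwise, so the observed sharing fraction equals
  the planted Bernoulli draw exactly. A standalone 400-pair fixture gives
  the sharing statistic a tight binomial error (±0.025 SD).

All outputs are pure functions of (config, seed); seeds for the PWM,
genome and ontology components derive from independent spawn streams so
adding one component never perturbs another.

What the generator does **not** emulate: isochore and repeat structure,
realistic gene density and length distributions, multi-transcript TSS
heterogeneity, convergent/tandem proximity classes (beyond what isolation
spacing implies), annotation bias, or motif instances degraded away from
consensus. Passing tests on this synthetic study therefore demonstrate
correctness of the *method* — exact rule boundaries, oracle-equal scanning
and island finding, recovery of planted signal — not performance on real
genomes, where signal-to-noise is far less favourable.

## Pipeline and problem sizes

The pipeline writes plain TSV/BED/FASTA artifacts per stage plus a run log
containing the full parameter set and a SHA-256 digest prefix of every
input; no timestamps are written, so reruns with the same configuration are
byte-identical. Later stages read earlier stages' files, which is what
makes `--from <stage>` resumption work.

Default problem sizes used throughout the tests and the acceptance script:
the 60-gene synthetic study (15 pairs / 30 uni-directional genes, ~45 kb of
promoter sequence), 200 random sequences of 500–700 bp for the island-finder
oracle, an exhaustive hypergeometric sweep over all margins with N ≤ 12,
and 100 random sequences × 3 motifs × 3 thresholds for the scanner oracle.
These sizes keep the full suite under a minute while leaving every
statistical conclusion (fold categories, sharing fraction) several standard
deviations away from its decision boundary.

## Known limitations

* The exact TSS-adjacency rule is ambiguous when two clusters share a TSS
  coordinate; the implementation uses a deterministic sort
  (TSS, strand, span start) and pairs consecutive entries, which resolves
  ties arbitrarily but reproducibly.
* The island finder's trim rule (greedy 1 bp from the end that most
  improves the failing statistic) is one of several defensible choices; a
  different tie-break would occasionally report slightly different island
  boundaries, never a different covered/uncovered decision for clearly
  qualifying regions.
* Enrichment treats gene symbols as identifiers; no synonym or ID-mapping
  layer is provided.
* Scanning scores every window independently; cooperative or spaced motif
  arrangements are out of scope.
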