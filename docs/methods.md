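# Methods

`lncarch` analyses how long non-coding RNA (lncRNA) genes are positioned
relative to their nearest protein-coding neighbours, and how the two
partners' expression evolves over a short differentiation timecourse.
This note documents the models, the parameters that matter, the numeric
conventions, and the deliberate design choices made where the design was
genuinely open.

## Coordinate and annotation model

All internal coordinates are 0-based half-open on the forward strand;
GFF3's 1-based closed convention is converted at the I/O edge
(`start - 1`, `end`), BED's native half-open coordinates pass through
unchanged. Genes are collapsed to one representative per locus: when an
annotation carries several transcripts, the gene span and the exon set
are the unions over transcripts (merged where overlapping). The pipeline
is deliberately gene-level — isoform-specific overlap is out of scope.
A gene's TSS is its `start` on `+` and its `end` on `-`.

## Pairing and the 19-class architecture taxonomy

Each lncRNA is paired with the protein-coding gene on the same chromosome
minimising the closest-edge distance, with overlap counting as distance
0; pairs farther than the association radius (default **10 kbp**) are
unassociated. Distance ties are broken by the more specific architecture
class, then by lexicographic gene id, so classification is deterministic.

The pair is then assigned exactly one of 19 classes by a first-match rule
cascade (overlap classes → promoter-resident → bidirectional →
intergenic); `upstream`/`downstream` are always relative to the
*protein's* strand. The classes and their five super-classes:

| super-class | classes |
|---|---|
| antisense | embedding_{sense,antisense}, exonic_{sense,antisense}, head_to_head, tail_to_tail |
| intronic | intronic_{sense,antisense} |
| promoter_associated | promoter_associated_{sense,antisense} |
| bidirectional | bidirectional_promoter_{1,5,10}kbp |
| intergenic | intergenic_{upstream,downstream}_{1,5,10}kbp |

Key conventions, chosen where several readings were defensible:

* **Exonic vs partial overlaps.** `exonic_*` requires the lncRNA to be
  contained in the protein span with a purely exonic overlap;
  `embedding_*` is containment touching both exon and intron. Partial
  (non-containment) antisense overlaps are `head_to_head` (5'-5') or
  `tail_to_tail` (3'-3') regardless of exonic content — for antisense
  partial overlaps the overlapped ends are always of the same type, so
  the two labels are exhaustive. Same-strand partial overlaps (a
  head-to-tail geometry no class names) resolve to `exonic_sense` /
  `embedding_sense` by exonic content, keeping the rule total.
* **Promoter-resident vs bidirectional.** Any non-overlapping antisense
  lncRNA on the protein's 5' side is geometrically divergent, so
  "antisense and promoter-proximal" alone cannot separate the two
  groups. We define `promoter_associated_*` as a lncRNA lying *entirely
  inside* the 1 kbp window immediately upstream of the protein TSS — a
  short promoter-resident RNA, on either strand — while divergent
  transcripts extending beyond the window are `bidirectional_promoter_*`,
  binned by TSS-to-TSS distance. This is the package's own convention;
  it is the only reading we found that makes all 19 classes
  simultaneously non-empty and mutually exclusive. It is also the least
  certain element of the taxonomy.
* **Distance bins** are exclusive: (0, 1000], (1000, 5000],
  (5000, 10000] bp — TSS-to-TSS for bidirectional classes (promoter
  sharing is a TSS property), closest-edge for intergenic classes. Genes
  that abut exactly (gap 0 without overlap) fall into the 1 kbp bin.
* The super-class grouping places the sense embedding/exonic subtypes in
  the *antisense* (overlap-architecture) super-class: the group describes
  overlap topology, and orientation is carried separately on each class.

Classification is invariant under genome reflection with strand flip
(mirror symmetry), tested property-style.

## Differential expression

The design is a replicated 4-point timecourse (0, 6, 24, 120 h; two
biological replicates; linear-scale array intensities, deliberately
**unnormalized** — a pass-through hook exists for user normalizers). A
gene is differentially expressed when both of:

1. **Replicate concordance**: for every replicate pair there is some
   3-subset of the 4 timepoints on which Kendall's τ between the two
   replicate profiles exceeds **0.6**. On 3 untied points τ ∈ {±1, ±1/3},
   so the threshold means perfect rank agreement on that subset.
2. **Fold change**: the ratio of replicate-mean intensities between the
   first and last timepoint, direction-symmetric (max/min), is ≥ **1.5**.

Kendall's τ uses the τ-b tie correction (the thresholds were designed for
untied data; τ-b keeps the rule robust on tied synthetic integers). With
more than two replicates the subset condition must hold for every
replicate pair — a conservative generalization.

lncRNA–protein **pair correlation** is Kendall's τ between the two
replicate-mean 4-point profiles: "+" at τ ≥ 0.6, "−" at τ ≤ −0.6. On 4
untied points τ ∈ {0, ±1/3, ±2/3, ±1}, so the cutoff admits exactly
|τ| ∈ {2/3, 1} (verified by exhaustive enumeration of all 24 orderings).

## Dynamic modes

Two eight-member template families describe a timecourse's shape:

* **rate** modes: all 2³ sign triples of change between consecutive
  timepoints; the numeric template is the cumulative sign path anchored
  at 0 (e.g. `(+,+,-) → (0,1,2,1)`). Signs come from per-timepoint
  medians; zero differences map to "−" (configurable) so the sign
  alphabet stays binary.
* **magnitude** modes: low/high 0/1 level patterns — the three up-steps,
  the 6–24 h pulse, and their four complements. Constant patterns are
  excluded (Pearson correlation against them is undefined); the set is
  closed under complementation.

A profile (replicate means by default, medians optionally) is assigned
the template with the highest Pearson correlation; ties break by catalog
order with a flag; constant profiles are "unassignable" rather than an
error. Templates are indexed by timepoint *rank*, not hours — with the
uneven 0/6/24/120 h grid, hour-indexing would silently down-weight the
early intervals; the modes are ordinal patterns. No cross-family pair of
templates is affine-equivalent (checked over all 8×8 pairs), so the two
families are genuinely distinct classifiers.

**Noise behaviour.** With Gaussian noise of σ = 0.2 added to unit-range
templates, family-aggregate recovery over 1,000 simulations per mode is
≈ 0.93 (rate) and ≈ 0.97 (magnitude), degrading monotonically with σ.
The zig-zag rate templates (`(+,-,+)`, `(-,+,-)`) are intrinsically
hardest (per-mode ≈ 0.86 at σ = 0.2): unit-range scaling concentrates
their whole dynamic range into single intervals, so equal-σ noise hurts
them most. Recovery guarantees are therefore stated per family, not per
mode.

## Filtration cascade and enrichment

Five nested memberships: (1) on the array → (2) differentially
expressed → (3) protein-associated → (4) partner also DE → (5) sign-
correlated with the partner. Correlation signs exist only inside set 4.
Per-step frequency tables over classes, super-classes and modes always
sum to the step's set size (unassociated lncRNAs are tabulated as
`(none)`).

At each step, each class's frequency among retained lncRNAs is
contrasted with its frequency among those removed at that step, with an
exact hypergeometric tail (over: P(X ≥ k); under: P(X ≤ k)); the smaller
tail is reported with its direction. Effect size is the fold enrichment
FE = (k/n) / ((K−k)/(N−n)) — retained frequency over removed frequency
(∞ when the class is absent from the removed set, flagged). Two
tabulations: class vs all non-members, and class vs one other class
(population restricted to the two). Bonferroni correction uses m = the
number of tests in the invocation batch (one step × one tabulation ×
all labels) — a reproducible, conservative family definition. Tails are
computed with exact integer binomials (one terminal division), falling
back to scipy's log-space implementation above N = 10,000.

## Synthetic data generator

The generator defines the study conditions every test runs under: two
replicates at 0/6/24/120 h, baseline intensity 100, 10× dynamic range,
noise σ = 0.2 on the unit template scale (truncated at 0 so intensities
stay positive), one pair per architecture class, planted correlation
signs drawn 0.4/0.4/0.2 for +/−/none.

Architectures are *constructed*, not rejection-sampled: each class has a
direct placement recipe in a local frame around a 3-exon reference
protein (distances drawn inside the correct bin, overlaps built per
class), reflected for minus-strand proteins; pair groups are separated
by more than radius + spacing so partner-finding is unambiguous. Because
the construction path shares no code with the classifier's predicates,
the planted-class = recovered-class round-trip (100% at any seed) is a
genuine two-implementation check.

Timecourses plant a protein mode template and give the lncRNA the same
template ("+"), its complement ("−" — both families are closed under
complementation), or a decoy template with |τ| < 0.6 against the partner
("none"), each with independent per-replicate noise. At σ = 0 mode,
sign, and (for the rate family, whose templates never have equal
endpoints) DE recovery are exact by construction.

**What the generator does not emulate:** probe-level effects,
cross-hybridization, intensity-dependent noise, missing values,
realistic genome-wide class frequencies, or inter-pair genomic
clutter (each lncRNA has exactly one candidate partner). Passing
round-trip tests therefore demonstrates the correctness of the
classification and template-matching logic under the stated geometry
and noise model, not performance on real array data.

## Problem sizes

Default test and verification sizes are chosen to be exhaustive where
exhaustion is cheap and Monte-Carlo elsewhere: all hypergeometric
parameterizations with N ≤ 25 against an exact-rational oracle; 1,000
random vectors for the Kendall oracle; 10,000 random profiles for the
assignment argmax oracle; 1,000 simulations per mode per σ for recovery
curves; 100 random datasets for cascade integrity.

## Known limitations

* The 19-class taxonomy, the promoter-resident definition, and the
  magnitude-mode signature set are reconstructions of a prose-level
  description; alternative readings exist (configurable radius, bins and
  promoter window mitigate this).
* Pair correlation on 4 points is extremely coarse (seven attainable τ
  values); it is a screen, not an estimate.
* The first/last fold-change rule is blind to transient regulation; the
  transient magnitude modes can be called non-DE even noise-free.
* Bonferroni families are batch-scoped; combining batches requires the
  caller to re-correct.
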