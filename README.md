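# lncarch

Genomic-architecture classification of lncRNA / protein-coding gene
pairs, and expression-dynamics analysis of replicated short timecourses.

Long non-coding RNAs frequently act in *cis*: their function correlates
with where they sit relative to neighbouring protein-coding genes —
antisense overlap, residence in an intron, a shared bidirectional
promoter, or plain intergenic proximity — and with whether their
expression tracks (or mirrors) that neighbour's. `lncarch` provides a
reusable, fully testable pipeline for this kind of integrated analysis:

* **Pairing and classification** — each lncRNA gene is paired with its
  closest protein-coding gene within 10 kbp (overlap = distance 0) and
  assigned one of **19 genomic-architecture classes** collapsing onto 5
  super-classes (antisense, intronic, intergenic, bidirectional,
  promoter-associated), with exclusive distance bins (0–1, 1–5,
  5–10 kbp).
* **Differential expression** — from a replicated 4-point timecourse
  (0/6/24/120 h, ≥2 biological replicates): a gene is DE when its
  replicates are rank-concordant on some three of the four timepoints
  (Kendall's τ > 0.6) and the first-to-last fold change is ≥ 1.5.
* **Dynamic modes** — each profile is matched by Pearson correlation
  against 8 "rate" templates (all sign triples of interval changes) and
  8 "magnitude" templates (low/high step and pulse patterns).
* **Pair correlation and filtration cascade** — signed lncRNA–protein
  correlation (|τ| ≥ 0.6) and the nested cascade *on array → DE →
  protein-associated → partner DE → correlated*, with per-step class and
  mode frequency tables.
* **Enrichment** — exact hypergeometric over/under-representation of a
  class among retained vs removed lncRNAs at each cascade step, fold
  enrichment FE = (k/n)/((K−k)/(N−n)), Bonferroni-corrected.
* **Synthetic data** — a generator that plants known architectures,
  modes, and correlation signs, so every stage is verifiable end to end
  with no external data.

The model and all conventions are documented in
[`docs/methods.md`](docs/methods.md).

## Worked example

Simulate a dataset with one planted pair per architecture class, then
classify and analyze it:

```sh
lncarch simulate --seed 11 --out demo/sim
lncarch classify --gff demo/sim/annotations.gff3 --out demo/cls
lncarch analyze --pairs demo/cls/pairs.tsv --expr demo/sim/expression.tsv --out demo/ana
```

`classify` logs `19 pairs classified, 0 lncRNAs unassociated` and writes
`pairs.tsv`:

```
lncrna_id                   partner_id                  ga_class            superclass  edge_distance  tss_distance  overlap_bp
lnc_intronic_sense_000      prot_intronic_sense_000     intronic_sense      intronic    0              1768          1094
lnc_intronic_antisense_000  prot_intronic_antisense_000 intronic_antisense  intronic    0              2155          830
lnc_exonic_sense_000        prot_exonic_sense_000       exonic_sense        antisense   0              3721          121
...
```

Every lncRNA found a partner (`edge_distance` 0 means overlap), and the
recovered `ga_class` column matches the generator's truth table exactly.
`analyze` then reports the nested cascade sizes

```
cascade sizes: {'on_array': 19, 'differentially_expressed': 12,
'protein_associated': 12, 'partner_differentially_expressed': 11, 'correlated': 6}
```

— at the default noise level (σ = 0.2) 12 of the 19 lncRNAs pass the DE
rule, 11 of those have DE partners, and 6 correlate with their partner at
|τ| ≥ 0.6. The enrichment report (`enrichment.tsv`) contrasts each class
and mode between retained and removed sets at every step; its top line at
the final step,

```
step        label                        k  K  n  N   direction  p_value   fold_enrichment  p_adjusted
correlated  permanently_activated_by_6h  4  4  6  11  over       0.045455  inf              0.318182
```

reads: all 4 lncRNAs whose rate mode was "permanently activated by 6 h"
survived the correlation filter (k=4 of K=4, retained n=6 of N=11 — the
mode is absent from the removed set, hence the infinite fold enrichment);
the hypergeometric tail is p ≈ 0.045 before and 0.32 after Bonferroni
correction across the 7 modes tested in the batch.

The same analysis is available as a library — `classify_all`,
`is_differentially_expressed`, `assign_mode`, `correlate_pair`,
`run_filtration_cascade`, `class_shift_tests` — see the module
docstrings.

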