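# restoromics

A tested, reusable pipeline for evaluating therapeutic protein restoration
from multiplexed isobaric-label (TMT-style) proteomics:

* **construct_peptides** — in-silico tryptic digestion (full specificity,
  missed-cleavage budget, length bounds) and classification of peptides into
  construct-discriminating panels (`PAN`, `FULL_ONLY`, `TRANSGENIC_SHARED`,
  `LARGE_ONLY`, `OTHER`), plus panel-level quantification.
* **normalization_qc** — within-plex channel-total equalization, per-protein
  inter-plex scaling via pooled bridge channels (geometric-mean bridging),
  pooled-missing exclusion, minimum-peptide filtering, Grubbs single-outlier
  removal, and razor-rule peptide→protein roll-up.
* **differential_stats** — geometric-mean log2 fold changes, two-sided
  unpaired t-tests (Student default, Welch optional), Benjamini–Hochberg
  FDR, DEP calling at configurable cutoffs (default |log2FC| ≥ 1, q ≤ 0.05),
  volcano tables, and per-protein one-way ANOVA with Tukey HSD.
* **restoration** — Venn set partitions over DEP lists and a per-treatment
  taxonomy (`restored` / `partial` / `unrestored` / `treatment_induced` /
  `unchanged`) with summary counts, plus the end-to-end pipeline runner.
* **synthetic_data** — a ground-truthed study simulator (5 groups × 6
  replicates split across two 16-channel plexes, one pooled bridge per plex)
  with planted differential proteins, restoration profiles, plex batch
  shifts, coisolation mixing, log-normal noise, outliers, and missingness —
  so the whole pipeline is testable offline.
* **core_io** — typed domain objects and plain-text I/O (FASTA constructs
  with `origin=`/`size_class=` header tags, wide abundance TSVs, sample
  sheets, JSON run configuration).

## CLI

```bash
# generate a synthetic study (abundance.tsv, samples.tsv, truth.json)
restoromics simulate --seed 1 --out-dir sim/

# sanity-check a table against its sample sheet
restoromics validate sim/abundance.tsv sim/samples.tsv

# digest constructs and write peptide -> panel assignments
restoromics classify-peptides constructs.fasta --out panels.tsv

# normalization + QC only
restoromics normalize sim/abundance.tsv sim/samples.tsv --out-dir norm/

# differential expression (one contrast, or the full 10-contrast set)
restoromics dep norm/normalized_matrix.tsv sim/samples.tsv \
    --contrast mdx_saline:WT --out dep_mdx_vs_WT.tsv
restoromics dep norm/normalized_matrix.tsv sim/samples.tsv \
    --all-contrasts --out dep/

# restoration taxonomy from precomputed DEP tables
restoromics restore --dep-dir dep/ --out restoration.tsv

# everything at once: normalize -> filters -> DEPs -> restoration bundle
restoromics run --table sim/abundance.tsv --sheet sim/samples.tsv \
    --config run.json --out-dir results/
```

Group labels are fixed: `WT`, `mdx_saline`, `uDys`, `midiDys`, `fullDys`,
plus `POOL` for bridge channels (exactly one per plex). A run config JSON
may set `fc_cutoff_log2`, `q_cutoff`, `grubbs_alpha`, `min_peptides`,
`contrasts`, `equal_var`, and `seed`.

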