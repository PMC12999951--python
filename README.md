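# repliskew

Nucleotide-skew analysis of prokaryotic replicons:

- **Windowed and cumulative GC skew** `(G − C)/(G + C)` in fixed windows
  (default 4,096 bases), decomposed by codon position (1st/2nd/3rd) and
  coding status (non-coding sub-skew).
- **Gene strand bias (GSB)**: a cumulative per-nucleotide counter (+1 inside
  plus-strand genes, −1 inside minus-strand genes) sampled on the same
  window grid.
- **SkewI**: a single value in [0, 1] scoring how well window-level skew
  signs match an ideal two-replichore pattern, maximized over circular
  rotations (default 20 kb windows, with the complete-and-≥500 kb QC rule).
- **div**: the predicted leading-strand fraction, from an exhaustive-search
  two-breakpoint piecewise-linear fit (with drift term) of the cumulative
  total skew.
- **Correlation framework**: per-replicon Pearson correlations of the GSB
  curve against each cumulative sub-skew, class-level aggregation
  (mean, SD, CV%, fraction of PCC > 0.5), single-strand G/C parity
  regression, and Mann–Whitney / Kruskal–Wallis / ANOVA group comparisons
  with Holm-adjusted post-hocs.
- **Synthetic generator**: circular replicons with a chosen origin/terminus,
  strand-specific leading-strand G enrichment (`beta`), tunable gene
  co-orientation bias (`p_lead`), and codon-position-specific nucleotide
  weights — with ground truth for recovery tests.

## CLI

```bash
# one genome -> JSON record (SkewI, div, PCC set) + optional curve TSV
repliskew analyze genome.fasta --annotation genome.gff3 \
    --out record.json --curves curves.tsv

# batch over a manifest TSV (columns: fasta, annotation, class_label)
repliskew batch manifest.tsv --out-dir batch_out/

# synthetic annotated replicon (FASTA + GFF3 + ground-truth JSON)
repliskew simulate --out-dir synthetic/ --seed 7

# rebuild class-level summary tables from a records TSV
repliskew summarize batch_out/records.tsv --out class_summary.tsv
```

`python -m repliskew.cli --help` works without the console script.

## Library sketch

```python
from repliskew import (
    read_replicons, read_features, build_position_labels,
    windowed_skew, cumulative_profile, gsb_profile,
    skew_index, fit_div, replicon_correlation_set,
    SyntheticConfig, simulate_replicon,
)

(rep,) = read_replicons("genome.fasta")
feats = read_features("genome.gff3")
labels = build_position_labels(rep, feats)
cum = cumulative_profile(windowed_skew(rep, labels, "total", 4096))
print(skew_index(rep).skewi, fit_div(cum).div)
print(replicon_correlation_set(rep, feats))
```
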