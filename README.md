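# dielshift

Comparative diel-rhythmicity analysis for two-condition expression
timecourses (well-watered `WW` vs drought `DR`), built around a 24-h design
sampled every 2 h with replicates:

* **Rhythm detection** — JTK-style nonparametric cosine-template matching
  with Kendall's S, exact tie-aware null distributions (dynamic-programming
  convolution), Bonferroni cycling calls, and least-squares phase/amplitude
  estimates.
* **Rhythm-change classification** — per-gene categories (cycling in one
  condition, both with equal/changed amplitude, arrhythmic), circular phase
  shifts, and per-phase hypergeometric enrichment of gene groups.
* **Promoter element discovery** — promoter extraction from genome + gene
  models (BED6/GFF3), IUPAC motif scanning over both strands, and
  exhaustive canonical 3–8-mer presence enrichment.
* **Network comparison** — signed weighted co-expression networks (biweight
  midcorrelation, topological overlap, module detection and merging),
  cross-condition module overlap with Fisher's exact test, normalized
  mutual-information interaction networks with data-processing-inequality
  pruning, and activator/suppressor classification of condition-specific
  partners.
* **Synthetic data** — ground-truth generators for diel expression
  matrices, promoters with planted motifs, and network-structured samples,
  so every stage is testable end to end without external data.
* **Aux metrics** — gene-family expansion/contraction ratios, titratable
  acidity, stomatal aperture, and Ks-based divergence time.

## CLI

```sh
# simulate a two-condition timecourse with known truth
dielshift simulate --seed 1 --out sim/

# rhythm calls per condition (filter + JTK-style scan + Bonferroni)
dielshift rhythm --matrix sim/expression.tsv --condition WW --out calls_ww.tsv
dielshift rhythm --matrix sim/expression.tsv --condition DR --out calls_dr.tsv

# rhythm-change categories and summary table
dielshift compare --calls-ww calls_ww.tsv --calls-dr calls_dr.tsv --out-prefix cmp

# promoter k-mer enrichment (promoter FASTA, or --genome + --models)
dielshift elements --promoters promoters.fa --fg fg.txt --bg bg.txt --out enrich.tsv

# co-expression modules + interaction network for one condition
dielshift network --matrix sim/expression.tsv --condition WW --out-prefix net_ww

# closed-form metrics
dielshift aux acid 1.0 1.0
dielshift aux kstime 0.026 1.5e-8
```

Analysis thresholds (filter, alpha, amplitude/phase thresholds, network
powers/heights/thresholds) have sensible defaults and can be overridden via
a YAML config (`dielshift.core_io.load_config`).

## Notes on method stand-ins

The interaction-network scorer is a normalized mutual-information + DPI
stand-in for part-mutual-information programs: it reproduces the
condition-differencing logic (activator/suppressor calls), not any specific
tool's edge scores. Module detection uses a fixed-height cut plus
representative-profile merging rather than dynamic tree cutting; the
module-overlap statistics downstream are the supported output.
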