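# brmtls

Analysis of the tumor-immune microenvironment and tertiary lymphoid
structures (TLS) in brain metastases (BrM), for computational biologists
studying immune infiltration in metastatic brain tumors from bulk RNA-seq
and multiplex immunofluorescence (mIF) data.

TLS are ectopic, lymph-node-like aggregates of B and T lymphocytes with
dendritic cells that form in non-lymphoid tissue and are associated with
immunotherapy response and prognosis across cancers. The package covers the
full desk-side pipeline:

- **Expression core** — RPKM/TPM normalisation
  (`RPKM(g,s) = count / (exon-length_kb × total-reads_millions)`), log2
  transform, per-gene z-scores, delimited-text I/O.
- **Deconvolution** — MCP-counter-style population scores
  (`score(s,p) = mean of log2 expression over p's markers`), the immune cell
  infiltration score `ICI(s) = Σ_immune score(s,p)` with tertile groups, and
  immune classes IC1..IC6 by Ward clustering of z-scored scores.
- **TLS signature** — a 46-gene candidate compendium from six published
  lists; cohort signatures built by Pearson correlation of each candidate
  with the 12-chemokine seed score, discarding low-expressed (< 1 TPM) and
  anti-correlated genes; per-sample score
  `exp(mean ln(TPM+1))` (geometric mean); TLS1/2/3 classes by Ward
  clustering; median-split high/low stratification; cytolytic score
  `mean(log2(GZMA+1), log2(PRF1+1))`.
- **Spatial TLS** — DBSCAN detection of lymphoid aggregates in phenotyped
  cell maps (µm coordinates), then the calling rules: perivascular ∧
  ≥ 500 cells ∧ B fraction > 50% → TLS; plus ≥ 1 Lamp3+ dendritic cell →
  intermediate TLS; a sample is TLS-positive iff it carries a qualifying
  aggregate.
- **Association statistics** — Mann-Whitney/Kruskal-Wallis,
  Benjamini-Hochberg, Pearson correlation, RNA-vs-mIF concordance,
  Kaplan-Meier/log-rank, a Newton-Raphson Cox proportional-hazards fit
  (Breslow ties) with forest tables, and binomial logistic enrichment.
- **Synthetic cohorts** — a seeded generator producing bulk counts, tissue
  maps with planted perivascular aggregates, and survival tables together
  with ground truth, so the whole pipeline is testable without any
  controlled-access download.

See `docs/methods.md` for the model, conventions and design choices.

## Worked example

```python
import brmtls as b

cfg = b.SimulationConfig(seed=1)
counts, lengths, truth = b.generate_bulk_cohort(cfg)
print("cohort:", counts.shape[0], "genes x", counts.shape[1], "samples;",
      int(truth.samples.tls_status.sum()), "TLS-positive")

tpm = b.compute_tpm(counts, lengths)
signature = b.build_signature(tpm)
print("signature:", len(signature), "genes; top gene:",
      signature.index[0], "r = %.3f" % signature.iloc[0]["r"])

score = b.metagene_score(tpm, list(signature.index))
classes = b.assign_tls_classes(tpm, list(signature.index))
level = b.median_split(score)
agree = ((level == "high") == truth.samples.tls_status).mean()
print("TLS classes:", classes.value_counts().to_dict())
print("median-split vs planted truth: %.1f%% agreement" % (100 * agree))

ici = b.compute_ici(
    b.score_populations(b.log_transform(tpm), b.DEFAULT_MARKERS), b.DEFAULT_MARKERS
)
print("mean ICI by site:", ici.score.groupby(truth.samples.site).mean().round(2).to_dict())
```

prints

```
cohort: 2075 genes x 95 samples; 20 TLS-positive
signature: 46 genes; top gene: CCL2 r = 0.969
TLS classes: {'TLS2': 56, 'TLS3': 20, 'TLS1': 19}
median-split vs planted truth: 71.6% agreement
mean ICI by site: {'breast': 50.61, 'colon': 53.66, 'kidney': 53.76, 'lung': 56.91, 'melanoma': 55.5}
```

Reading the output: all 46 compendium genes survive selection because the
generator elevates every TLS-related gene in TLS-positive samples; the 20
TLS-positive samples form exactly the TLS3 cluster; the median split caps at
~72% agreement here because only ~21% of the cohort is truly TLS-positive
while a median split labels half the cohort "high" (on a balanced-prevalence
cohort the same pipeline reaches ≥ 95%, see the acceptance metrics); and
mean ICI is ordered lung > melanoma > breast, mirroring the configured
site-level infiltration.

The same pipeline runs from the shell:

```bash
brmtls simulate  --seed 11 --out-dir out/sim
brmtls deconvolve --expression out/sim/expression_counts.tsv \
                  --lengths out/sim/gene_lengths.tsv --out-dir out/dec
brmtls signature  --expression out/sim/expression_counts.tsv \
                  --lengths out/sim/gene_lengths.tsv --out-dir out/sig
brmtls spatial    --cells out/sim/cells.csv --vessels out/sim/vessels.csv \
                  --out-dir out/spa
brmtls survival   --clinical out/sim/clinical.tsv --out-dir out/sur
```

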