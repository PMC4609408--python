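# mirimprint

Tools for asking whether the microRNAs that distinguish pluripotent cells
(hiPSCs and hESCs) from the fibroblasts they were derived from are not just
differentially expressed but *genomically organised* — sitting in tight
chromosomal clusters — and whether imprinted genes co-locate with those
clusters more often than chance placement explains. Imprinted regions such
as DLK1–DIO3 (14q32) are known markers of pluripotency quality, so the
co-location question is of direct interest to stem-cell researchers with
miRNA expression profiles in hand.

The package implements the full analysis chain as a tested library plus CLI:

1. **Differential expression** (`mirimprint.de`). For each pairwise
   cell-type contrast a moderated two-sample t-test on log2 intensities:
   per-miRNA pooled variances s² (d df) are shrunk towards a moment-fitted
   prior (d0, s0²),

       s̃² = (d0·s0² + d·s²) / (d0 + d),
       t = (x̄_A − x̄_B) / sqrt(s̃²(1/n_A + 1/n_B)),

   with p-values on d0 + d df and Benjamini–Hochberg FDR. miRNAs significant
   versus the reference in *both* pluripotent contrasts (FDR ≤ 0.05), with an
   optional per-contrast 2-fold filter, form the pluripotency DE set.
2. **Positional clustering** (`mirimprint.clustering`). DE miRNA positions
   on each chromosome are organised into a positional distance tree
   (1-D single linkage by adjacent gaps); every node is a candidate cluster
   scored by the closed form

       P = 1 − (1 − M·D/L)^N

   where L is chromosome length, M the number of profiled miRNAs on that
   chromosome, D the largest gap between position-adjacent members, and N
   the number of DE members. Nodes with P ≤ 0.1 and N ≥ 3 pass; the largest
   passing node on each path is reported, giving disjoint clusters.
3. **Imprinted-gene enrichment** (`mirimprint.enrichment`). Count imprinted
   genes within 6 Mbp of any cluster, then build a null by drawing 1000
   random miRNA sets of the same size from all profiled loci, re-clustering
   each, and counting again. The empirical p-value is the fraction of
   permutations whose count strictly exceeds the observed one.
4. **Synthetic data** (`mirimprint.simulate`). A generator for genomes,
   miRNA/imprinted-gene coordinates (BED), and expression matrices with
   planted DE effects and planted spatial co-location, so the whole chain is
   testable without any external download.

## Worked example

```python
from mirimprint import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(outdir="demo", sim=SimulationConfig(seed=1), seed=1, n_perm=1000)
paths = run_pipeline(cfg)
print(open(paths["report"]).read())
```

The log of that run prints:

```
stage de: both=133, both>=2-fold=59, discordant=13
stage cluster: 12 clusters
stage enrich: observed=38 empirical_p=0
```

meaning: of 800 simulated miRNAs, 133 were significant versus fibroblasts in
both pluripotent contrasts (131 were planted), 59 of them at ≥2-fold in both;
the positional scan found the 12 planted clusters (60 member miRNAs); 38 of
the 210 imprinted genes lie within 6 Mbp of a cluster, while no random
miRNA set out of 1000 permutations got more than the observed count —
empirical p = 0/1000, strong evidence of co-location (which the generator
indeed planted). `demo/report.md` holds the same numbers as a readable
report, next to `de_results.tsv`, `clusters.tsv`/`.bed` and
`enrichment.json`.

The same run, stage by stage, from a shell:

```
mirimprint simulate --outdir demo --seed 1
mirimprint de --expr demo/expression.tsv --samples demo/samples.tsv
mirimprint cluster --de de_sets.json --mirnas demo/miRNAs.bed --chrom-sizes demo/chrom.sizes
mirimprint enrich --clusters clusters.tsv --mirnas demo/miRNAs.bed \
    --imprinted demo/imprinted.bed --chrom-sizes demo/chrom.sizes --de de_sets.json
```

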