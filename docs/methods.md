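# Methods

## The statistical model, stage by stage

### Moderated differential expression

Input is a log2-intensity matrix (miRNA × sample) with samples grouped into
three cell types: a reference (NHDF, normal human dermal fibroblasts) and
two pluripotent types (iPSC, ESC). Lines within a group are treated as
exchangeable replicates — the analysis pools all iPSC variants into one
category, so no line-level blocking is modelled.

Each pairwise contrast is the two-group special case of the empirical-Bayes
linear model standard in microarray analysis. With group sizes n_A, n_B and
pooled residual variance s² on d = n_A + n_B − 2 df per miRNA, the variance
prior (d0, s0²) is fitted by the method of moments on z = log s²: writing
e = z − ψ(d/2) + log(d/2), the excess of var(e) over ψ′(d/2) identifies
d0 through the trigamma inverse, and mean(e) then identifies s0². When the
observed spread of log variances does not exceed sampling noise, d0 = ∞ and
every miRNA receives the common variance s0² (this happens by construction
on homoscedastic simulated data and is the correct limit). The moderated
statistic is t = Δx̄ / sqrt(s̃²(1/n_A + 1/n_B)) with
s̃² = (d0 s0² + d s²)/(d0 + d), referred to a t distribution on d0 + d df,
capped at the total pooled df across miRNAs. The implementation reproduces
Bioconductor limma's `lmFit`+`eBayes` on the same matrix to ~1e-14 (checked
in the test suite with limma as an independent oracle via Rscript).

Benjamini–Hochberg FDR is applied per contrast (delegated to
`statsmodels.stats.multitest`; a brute-force step-up implementation serves
as the test oracle). Contrast combination is pure set algebra:

- `both` — FDR ≤ 0.05 in both versus-reference contrasts (the
  pluripotency-associated set);
- `both_min_fold` — additionally |log2FC| ≥ log2(fold) in *each* of the two
  contrasts (per-contrast is the stricter of the possible readings of an
  "at least 2-fold" filter, and the one implemented);
- `discordant` — significant in exactly one of the two (the symmetric
  difference), the natural operationalisation of "significant in one cell
  type and only slightly in the other" absent a numeric definition of
  "slightly".

### Positional cluster scan

miRNA loci are reduced to points (interval starts; at the ~Mb scales that
matter here the ~80 bp locus extent is irrelevant). Per chromosome the DE
positions are built into a positional distance tree: 1-D single-linkage
agglomeration, merging adjacent runs in ascending order of the gaps between
them. For 1-D points this is exact single linkage, and it has the useful
property that a node's merge height equals the maximum adjacent gap D among
its members. Gap ties merge left to right, making the tree deterministic
and input-order invariant. Loci at identical coordinates (polycistronic
annotations) stay distinct members with gap 0.

Every tree node is a candidate cluster scored by P = 1 − (1 − q)^N with
q = M·D/L clamped to [0, 1]: under uniform random placement of M loci on a
chromosome of length L, q approximates the chance that one point has a
neighbour within D, and P is the chance that at least one of N independent
such trials succeeds. D can exceed L/M in degenerate candidates, hence the
clamp. The closed form is pinned against a Monte-Carlo Bernoulli oracle in
the tests. P is monotone non-decreasing in both D and N.

Acceptance cutoffs are P ≤ 0.1 and N ≥ 3. Among nested significant nodes
the *topmost* (largest) passing node on each root-to-leaf path is reported:
the walk starts at the root and stops descending at the first passing node,
so reported clusters are disjoint maximal significant regions. Reporting
the smallest-P node per path was considered and rejected — the tightest
3-member core of a larger planted cluster almost always has smaller P than
the full cluster, so that rule systematically truncates real clusters;
maximal regions also match the intuition of reporting a dozen disjoint
clusters carrying several members each. M counts *all* profiled miRNAs on
the chromosome (DE or not); N counts DE members only.

### Imprinted-gene enrichment

A gene is "in or near" a cluster when its edge-to-edge distance to the
cluster interval is at most the proximity window w (default 6 Mbp) —
equivalently, when its interval overlaps the cluster expanded by w on both
sides, boundary inclusive (exactly w bp away counts; w+1 does not). Genes
are counted once regardless of how many clusters they are near. Gene
anchoring is whole-interval (edge-to-edge), the most inclusive choice given
no stated anchor (TSS vs interval).

The null resamples DE *labels*, not positions: each of n_perm (default
1000) permutations draws the same number of loci as the observed DE set,
uniformly without replacement from all profiled loci genome-wide
(unstratified), re-runs the identical cluster scan, and counts genes with
the identical window. The empirical p-value is the strict-exceedance
fraction #{count_perm > count_obs}/n_perm with no +1 correction — the
uncorrected ratio is what the reported quantity is defined as, and it is
exactly 0.037 for 37 exceedances in 1000.

## The synthetic-data generator

The generator emulates the statistical structure of a published miRNA
microarray study of pluripotency, and its defaults are that study's
conditions:

| parameter | default | meaning |
|---|---|---|
| `n_mirnas_total` | 800 | profiled miRNAs |
| `groups` | NHDF 1×3, iPSC 5×3, ESC 3×3 | lines × replicates → 27 samples |
| `de_fraction` | 131/800 | miRNAs given a pluripotency effect |
| `effect_log2fc` | 1.0 | group-mean shift (2-fold) in both pluripotent groups |
| `noise_sd` | 0.25 | Gaussian noise sd on log2 scale |
| `n_planted_clusters` | 12 | tight genomic clusters of DE miRNAs |
| `cluster_size` / `cluster_span` | 5 / 50 kb | members per cluster / window they occupy |
| `n_imprinted` | 210 | imprinted genes |
| `imprinted_near_cluster_fraction` | 30/210 | genes placed within the window of a planted cluster |
| `proximity_window` | 6 Mbp | the "near" definition |
| `chromosomes` | 24 human-like | GRCh38 lengths rounded to the Mb |

Choices made where the emulation target is silent: the 50 kb cluster span
reflects real pluripotency-associated miRNA clusters (miR-371/372/373 ~1 kb,
C19MC ~100 kb, the 14q32 cluster ~200 kb); spans near the per-chromosome
mean miRNA spacing (~4 Mb) would not be detectable by the scan statistic at
N = 5 and would not be called clusters by a biologist either. Baselines are
N(8, 1.5) on log2 scale, typical of normalised microarray intensities. Gene
lengths are uniform 5–50 kb. Planted effects are all upward in both
pluripotent groups, so the same set is DE in each versus-reference contrast
and the true versus-reference difference is exactly `effect_log2fc`.

Placement is uniform within chromosomes, chromosomes chosen proportionally
to length; planted clusters drop their members inside a uniformly placed
window. One global seed drives hierarchical per-stage sub-seeds
(`SeedSequence([seed, stage])`), so genome, placement and expression stages
are independently reproducible, and a fixed config + seed produces
byte-identical fixture bundles.

What the generator does **not** emulate: probe-level artifacts, batch
effects, normalisation (assumed upstream), line-level random effects,
correlated noise, and the intrinsic (non-planted) clustering of the real
miRNA complement — background loci are uniform unless clusters are planted.
Passing tests therefore demonstrate correctness of the algorithms and
calibration under the stated generative model, not robustness to every
property of real microarray data.

## Numerical and design notes

- P = 1 − (1 − q)^N is computed via `expm1`/`log1p` for small q.
- The trigamma inverse uses Newton iteration with asymptotic guards at both
  ends; a fully degenerate matrix (every miRNA flat) yields the point prior
  (∞, 0) and null statistics rather than an error.
- Zero-variance miRNAs are excluded from the prior fit but still receive a
  shrunken variance, so no division by zero occurs; a zero standard error
  with zero effect gives t = 0, p = 1.
- BED output is 0-based half-open; the clusters BED encodes
  round(−10·log10 P), capped at 1000, in the score column.
- Every writer emits a `#` provenance header (version, parameters, seed)
  which every reader skips; JSON outputs carry a `_provenance` object.
- All output formatting is fixed-precision, so identical config + seed gives
  byte-identical artifacts (asserted stage by stage in the tests).

## Test problem sizes

Statistical tests run on deliberately compact worlds: DE recovery uses the
full 800 × 27 default design over 20 seeds; cluster-detection power uses the
planted 5-in-50 kb / M = 40 / 100 Mb configuration over 20 seeds; the
enrichment null calibration uses 200 replicates of an 8 × 100 Mb genome with
300 loci in 24 clumps, 160 independent genes, and 200 permutations each.
The calibration world plants *locus* clumping but no gene co-location: with
uniformly scattered loci the permutation statistic degenerates at zero (no
random subset ever forms a significant cluster) and its p-value cannot be
uniform for any method; spatially clumped loci — which real miRNAs are —
keep the statistic non-degenerate while the null hypothesis (genes
independent of loci) still holds exactly.

## Known limitations

- The cluster p-value is an approximation, not an exact scan statistic; it
  is used as a ranking/thresholding device exactly as defined, and its
  calibration under the uniform null is checked only through the
  permutation layer on top of it.
- Strict-exceedance empirical p-values are discrete (granularity 1/n_perm)
  and slightly downward-biased under heavy ties; with 1000 permutations and
  a well-spread count statistic the effect is small, but p = 0 should be
  read as p < 1/n_perm.
- The moderated t assumes independent Gaussian log intensities; heavy
  tails or correlated probes would call for limma's robust options, which
  are out of scope here.
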