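"""Permutation test for imprinted-gene enrichment in/near miRNA clusters.

A gene counts as "in or nearby" a cluster when its edge-to-edge distance to
the cluster interval is at most the proximity window (default 6 Mbp); this is
interval overlap after expanding each cluster symmetrically by the window,
with the boundary inclusive (a gene exactly window bp away counts). The null
is built by resampling DE labels: each permutation draws the same number of
miRNA loci uniformly without replacement from all profiled loci (positions
fixed), re-runs the positional clustering with identical parameters, and
counts imprinted genes near the resulting clusters. The empirical p-value is
the strict-exceedance fraction — permutation counts strictly greater than the
observed count over the number of permutations, with no small-sample
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree

from .clustering import ClusterRegion, find_clusters
from .genome import GenomeModel, GenomicFeature

__all__ = [
    "EnrichmentResult",
    "count_imprinted_near_clusters",
    "permutation_enrichment_test",
    "empirical_pvalue",
]


def empirical_pvalue(exceedances: int, n_perm: int) -> float:
    """Fraction of permutations strictly exceeding the observation."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not (0 <= exceedances <= n_perm):
        raise ValueError("exceedances must lie in [0, n_perm]")
    return exceedances / n_perm


def count_imprinted_near_clusters(
    clusters: list[ClusterRegion],
    genes: list[GenomicFeature],
    window: int,
) -> int:
    """Number of distinct genes within ``window`` bp of any cluster.

    Distance is edge-to-edge on half-open intervals; a gene overlapping a
    cluster has distance 0, and a gene exactly ``window`` bp away counts.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    trees: dict[str, IntervalTree] = {}
    for c in clusters:
        # [start-w, end+w] closed expansion, +1 makes the upper edge inclusive
        trees.setdefault(c.chrom, IntervalTree()).addi(
            max(0, c.start - window), c.end + window + 1
        )
    count = 0
    for g in genes:
        tree = trees.get(g.chrom)
        # query end g.end + 1 makes the lower expanded edge inclusive too
        if tree is not None and tree.overlap(g.start, g.end + 1):
            count += 1
    return count


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed proximity count against its permutation null."""

    observed_count: int
    permutation_counts: tuple[int, ...]
    n_perm: int
    proximity_window: int
    empirical_p: float
    seed: int

    def __post_init__(self) -> None:
        if len(self.permutation_counts) != self.n_perm:
            raise ValueError("permutation_counts length must equal n_perm")
        exceed = sum(c > self.observed_count for c in self.permutation_counts)
        if abs(self.empirical_p - exceed / self.n_perm) > 1e-12:
            raise ValueError("empirical_p inconsistent with permutation counts")

    def to_dict(self) -> dict:
        return {
            "observed_count": self.observed_count,
            "n_perm": self.n_perm,
            "proximity_window": self.proximity_window,
            "empirical_p": self.empirical_p,
            "seed": self.seed,
            "permutation_counts": list(self.permutation_counts),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnrichmentResult":
        return cls(
            observed_count=int(d["observed_count"]),
            permutation_counts=tuple(int(c) for c in d["permutation_counts"]),
            n_perm=int(d["n_perm"]),
            proximity_window=int(d["proximity_window"]),
            empirical_p=float(d["empirical_p"]),
            seed=int(d["seed"]),
        )


def permutation_enrichment_test(
    all_loci: list[GenomicFeature],
    n_de: int,
    genes: list[GenomicFeature],
    genome: GenomeModel,
    observed_count: int,
    seed: int,
    *,
    n_perm: int = 1000,
    window: int = 6_000_000,
    p_cutoff: float = 0.1,
    n_min: int = 3,
) -> EnrichmentResult:
    """Permutation null for the imprinted-gene proximity count.

    Each permutation samples ``n_de`` loci uniformly without replacement from
    ``all_loci``, re-clusters them with the same parameters as the observed
    analysis, and counts genes within ``window`` of the resulting clusters.
    """
    if n_de > len(all_loci):
        raise ValueError(f"cannot sample {n_de} DE loci from {len(all_loci)} profiled")
    if observed_count < 0:
        raise ValueError("observed_count must be >= 0")
    rng = np.random.default_rng(seed)
    loci = np.asarray(all_loci, dtype=object)
    counts = []
    for _ in range(n_perm):
        idx = rng.choice(len(loci), size=n_de, replace=False)
        perm_de = list(loci[idx])
        perm_clusters = find_clusters(perm_de, all_loci, genome, p_cutoff, n_min)
        counts.append(count_imprinted_near_clusters(perm_clusters, genes, window))
    exceed = sum(c > observed_count for c in counts)
    return EnrichmentResult(
        observed_count=observed_count,
        permutation_counts=tuple(counts),
        n_perm=n_perm,
        proximity_window=window,
        empirical_p=empirical_pvalue(exceed, n_perm),
        seed=seed,
    )
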