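"""Positional clustering of DE miRNAs on chromosomes with a closed-form
cluster p-value.

miRNA loci are treated as points (interval starts) on each chromosome. The
differentially expressed loci are organised into a positional distance tree —
single-linkage agglomeration over 1-D positions, where merges happen in
ascending order of adjacent gaps — and every tree node is a candidate
cluster. A candidate with N members, maximum adjacent gap D, on a chromosome
of length L carrying M profiled miRNAs in total, is scored

    P = 1 − (1 − q)^N,   q = min(1, M·D/L)

the probability that at least one of N points, each independently given a
window of D among M points spread over L, lands that close to a neighbour by
chance. Small P means the members sit closer together than random placement
explains. Candidates pass with P ≤ p_cutoff and N ≥ n_min; on each
root-to-leaf path only the topmost (largest) passing node is reported, so the
reported clusters are disjoint maximal significant regions.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeModel, GenomicFeature

__all__ = [
    "PositionalTreeNode",
    "ClusterRegion",
    "cluster_pvalue",
    "build_positional_tree",
    "find_clusters",
]


def cluster_pvalue(m_chrom: int, chrom_length: int, max_gap: float, n_members: int) -> float:
    """Closed-form cluster p-value P = 1 − (1 − M·D/L)^N, q clamped to [0,1].

    Parameters
    ----------
    m_chrom
        M — number of profiled miRNAs on the whole chromosome (DE or not).
    chrom_length
        L — chromosome length in bp.
    max_gap
        D — maximum gap between position-adjacent cluster members, bp.
    n_members
        N — number of DE miRNAs in the candidate cluster.
    """
    if chrom_length <= 0:
        raise ValueError("chromosome length must be positive")
    if m_chrom < 1 or n_members < 1:
        raise ValueError("M and N must be >= 1")
    if max_gap < 0:
        raise ValueError("max gap D must be >= 0")
    q = m_chrom * max_gap / chrom_length
    if q >= 1.0:
        return 1.0
    # 1 - (1-q)^n via expm1/log1p for precision at small q
    return float(-math.expm1(n_members * math.log1p(-q)))


@dataclass(frozen=True)
class PositionalTreeNode:
    """A node of the positional distance tree over one chromosome.

    Leaves hold a single locus; an internal node's members are the union of
    its two children's, and ``height`` is the bp gap at which they merged.
    Because merges happen in ascending gap order, ``height`` equals the
    maximum adjacent gap inside the node (the D of the candidate cluster).
    """

    ids: tuple[str, ...]
    positions: tuple[int, ...]  # sorted ascending
    height: int
    children: tuple["PositionalTreeNode", ...] = ()

    @property
    def size(self) -> int:
        return len(self.ids)

    @property
    def max_gap(self) -> int:
        return self.height

    @property
    def is_leaf(self) -> bool:
        return not self.children


def build_positional_tree(positions, ids=None) -> PositionalTreeNode:
    """Single-linkage tree over 1-D positions by ascending adjacent gaps.

    Unsorted input is sorted internally (by position, then id, so the result
    is invariant to input order). Ties in gap size are merged left to right.
    """
    positions = list(positions)
    if not positions:
        raise ValueError("need at least one position")
    if ids is None:
        ids = [str(i) for i in range(len(positions))]
    ids = [str(i) for i in ids]
    if len(ids) != len(positions):
        raise ValueError("ids and positions must have equal length")
    order = sorted(range(len(positions)), key=lambda i: (positions[i], ids[i]))
    pos = [int(positions[i]) for i in order]
    idn = [ids[i] for i in order]

    nodes: list[PositionalTreeNode | None] = [
        PositionalTreeNode(ids=(idn[i],), positions=(pos[i],), height=0)
        for i in range(len(pos))
    ]
    # Union-find over contiguous runs; root[i] -> index of run representative.
    parent = list(range(len(pos)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    gaps = [(pos[i + 1] - pos[i], i) for i in range(len(pos) - 1)]
    for gap, i in sorted(gaps):
        left = find(i)
        right = find(i + 1)
        lnode, rnode = nodes[left], nodes[right]
        assert lnode is not None and rnode is not None
        merged = PositionalTreeNode(
            ids=lnode.ids + rnode.ids,
            positions=lnode.positions + rnode.positions,
            height=gap,
            children=(lnode, rnode),
        )
        parent[right] = left
        nodes[left] = merged
        nodes[right] = None
    return nodes[find(0)]  # type: ignore[return-value]


@dataclass(frozen=True)
class ClusterRegion:
    """An accepted miRNA cluster with the quantities entering its p-value."""

    chrom: str
    start: int
    end: int
    members: tuple[str, ...]  # ordered by position
    n_members: int  # N
    max_gap: int  # D
    n_chrom_mirnas: int  # M
    chrom_length: int  # L
    p_value: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("cluster must have at least one member")
        if not (0 <= self.max_gap <= self.end - self.start):
            raise ValueError("max gap must lie within the cluster span")
        if self.n_chrom_mirnas < self.n_members:
            raise ValueError("chromosome miRNA count M cannot be below member count N")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value out of [0, 1]")

    def recompute_pvalue(self) -> float:
        return cluster_pvalue(
            self.n_chrom_mirnas, self.chrom_length, self.max_gap, self.n_members
        )


def find_clusters(
    de_loci: list[GenomicFeature],
    all_loci: list[GenomicFeature],
    genome: GenomeModel,
    p_cutoff: float = 0.1,
    n_min: int = 3,
) -> list[ClusterRegion]:
    """Report disjoint significant DE-miRNA clusters per chromosome.

    Per chromosome a positional tree over the DE loci is built and walked
    from the root: the first node on each path with P ≤ ``p_cutoff`` and
    N ≥ ``n_min`` is reported and its descendants are not descended into,
    giving maximal non-nested significant regions. M counts all profiled
    loci on the chromosome, not just DE ones.
    """
    if not (0 < p_cutoff <= 1):
        raise ValueError("p_cutoff must lie in (0, 1]")
    if n_min < 1:
        raise ValueError("n_min must be >= 1")
    all_by_id = {f.name: f for f in all_loci}
    for f in list(all_loci) + list(de_loci):
        if f.chrom not in genome:
            raise ValueError(f"locus {f.name!r} on unknown chromosome {f.chrom!r}")
        if f.end > genome.length(f.chrom):
            raise ValueError(f"locus {f.name!r} extends past chromosome end")
    missing = [f.name for f in de_loci if f.name not in all_by_id]
    if missing:
        raise ValueError(f"DE loci absent from profiled loci: {missing[:5]}")

    m_per_chrom = Counter(f.chrom for f in all_loci)
    de_by_chrom: dict[str, list[GenomicFeature]] = {}
    for f in de_loci:
        de_by_chrom.setdefault(f.chrom, []).append(f)

    regions: list[ClusterRegion] = []
    for chrom in genome.names:
        feats = de_by_chrom.get(chrom)
        if not feats or len(feats) < n_min:
            continue
        length = genome.length(chrom)
        m = m_per_chrom[chrom]
        root = build_positional_tree([f.start for f in feats], [f.name for f in feats])
        by_id = {f.name: f for f in feats}

        def walk(node: PositionalTreeNode) -> None:
            p = cluster_pvalue(m, length, node.max_gap, node.size)
            if node.size >= n_min and p <= p_cutoff:
                members = node.ids  # already position-sorted
                regions.append(
                    ClusterRegion(
                        chrom=chrom,
                        start=min(by_id[i].start for i in members),
                        end=max(by_id[i].end for i in members),
                        members=members,
                        n_members=node.size,
                        max_gap=node.max_gap,
                        n_chrom_mirnas=m,
                        chrom_length=length,
                        p_value=p,
                    )
                )
                return
            for child in node.children:
                walk(child)

        walk(root)

    regions.sort(key=lambda r: (genome.names.index(r.chrom), r.start, r.end))
    return [
        ClusterRegion(**{**r.__dict__, "name": f"cluster_{i + 1:03d}"})
        for i, r in enumerate(regions)
    ]
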