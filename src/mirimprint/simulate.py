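"""Synthetic genomes, miRNA/imprinted-gene coordinates, and expression
matrices with planted effects.

The generator emulates the statistical structure of the study design the
pipeline was built for: 800 profiled miRNAs on a human-like 24-chromosome
genome, three cell-type groups (1 fibroblast line, 5 iPSC lines, 3 ESC lines,
three replicates each, 27 samples), 210 imprinted genes, a ±6 Mbp proximity
window. Planted effects are controlled by the config: a fraction of miRNAs
is differentially expressed between the pluripotent groups and the reference
fibroblasts; some of those DE miRNAs are laid down in tight genomic clusters;
a fraction of the imprinted genes is placed within the proximity window of a
planted cluster. Everything else is uniform background proportional to
chromosome length.

Noise is independent Gaussian on log2 intensities — the standard microarray
assumption matching the linear-model analysis downstream. Lines within a
group share the group mean (no line-level random effect).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeModel, GenomicFeature
from .de import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "HUMAN_KARYOTYPE",
    "make_genome",
    "place_features",
    "simulate_expression",
    "simulate_bundle",
    "write_fixture_bundle",
]

# Human autosomes + X/Y rounded to the Mb (GRCh38 scale).
HUMAN_KARYOTYPE: tuple[tuple[str, int], ...] = (
    ("chr1", 248_000_000), ("chr2", 242_000_000), ("chr3", 198_000_000),
    ("chr4", 190_000_000), ("chr5", 182_000_000), ("chr6", 171_000_000),
    ("chr7", 159_000_000), ("chr8", 145_000_000), ("chr9", 138_000_000),
    ("chr10", 134_000_000), ("chr11", 135_000_000), ("chr12", 133_000_000),
    ("chr13", 114_000_000), ("chr14", 107_000_000), ("chr15", 102_000_000),
    ("chr16", 90_000_000), ("chr17", 83_000_000), ("chr18", 80_000_000),
    ("chr19", 59_000_000), ("chr20", 64_000_000), ("chr21", 47_000_000),
    ("chr22", 51_000_000), ("chrX", 156_000_000), ("chrY", 57_000_000),
)

_GROUPS_DEFAULT: tuple[tuple[str, int, int], ...] = (
    ("NHDF", 1, 3),
    ("iPSC", 5, 3),
    ("ESC", 3, 3),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults emulate the target design: 800 miRNAs, 131/800 differentially
    expressed versus fibroblasts, 12 planted clusters of 5 DE miRNAs within
    50 kb each, 210 imprinted genes of which 30/210 sit within 6 Mbp of a
    planted cluster, log2 effect 1.0 (2-fold), noise sd 0.25 on log2 scale.
    """

    n_mirnas_total: int = 800
    n_planted_clusters: int = 12
    cluster_span: int = 50_000
    cluster_size: int = 5
    n_imprinted: int = 210
    imprinted_near_cluster_fraction: float = 30 / 210
    proximity_window: int = 6_000_000
    groups: tuple[tuple[str, int, int], ...] = _GROUPS_DEFAULT
    de_fraction: float = 131 / 800
    effect_log2fc: float = 1.0
    noise_sd: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    mirna_length: int = 80
    gene_length_range: tuple[int, int] = (5_000, 50_000)
    chromosomes: tuple[tuple[str, int], ...] = HUMAN_KARYOTYPE
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_mirnas_total,
            self.n_planted_clusters,
            self.n_imprinted,
            self.cluster_span,
            self.proximity_window,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts and spans must be non-negative")
        if self.n_planted_clusters > 0 and self.cluster_size < 3:
            raise ValueError("planted clusters need cluster_size >= 3")
        for frac in (self.imprinted_near_cluster_fraction, self.de_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_planted_de < self.n_clustered:
            raise ValueError(
                "planted cluster members must be a subset of planted DE miRNAs: "
                f"{self.n_clustered} clustered but only {self.n_planted_de} DE"
            )
        for g, n_lines, n_reps in self.groups:
            if n_reps < 1 or n_lines < 1:
                raise ValueError(f"group {g!r} must have >=1 line and >=1 replicate")
            if n_lines * n_reps < 2:
                raise ValueError(f"group {g!r} must have >=2 samples in total")

    @property
    def n_planted_de(self) -> int:
        return int(round(self.de_fraction * self.n_mirnas_total))

    @property
    def n_clustered(self) -> int:
        return self.n_planted_clusters * self.cluster_size

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of the planted effects, for recovery tests and audits."""

    de_mirnas: dict[str, tuple[str, ...]]  # per contrast label
    cluster_members: tuple[tuple[str, ...], ...]
    cluster_intervals: tuple[tuple[str, int, int], ...]  # chrom, start, end
    near_genes: tuple[str, ...]

    def all_de_ids(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for ids in self.de_mirnas.values():
            out |= frozenset(ids)
        return out

    def to_dict(self) -> dict:
        return {
            "de_mirnas": {k: list(v) for k, v in self.de_mirnas.items()},
            "cluster_members": [list(m) for m in self.cluster_members],
            "cluster_intervals": [list(iv) for iv in self.cluster_intervals],
            "near_genes": list(self.near_genes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlantedTruth":
        return cls(
            de_mirnas={k: tuple(v) for k, v in d["de_mirnas"].items()},
            cluster_members=tuple(tuple(m) for m in d["cluster_members"]),
            cluster_intervals=tuple(
                (str(c), int(s), int(e)) for c, s, e in d["cluster_intervals"]
            ),
            near_genes=tuple(d["near_genes"]),
        )


def _stage_rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # One global seed, hierarchical sub-seeds so stages reproduce independently.
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


def make_genome(config: SimulationConfig) -> GenomeModel:
    """Materialise the configured chromosomes (deterministic)."""
    return GenomeModel(chromosomes=config.chromosomes)


def _uniform_placements(
    rng: np.random.Generator, genome: GenomeModel, n: int, feat_len
) -> list[tuple[str, int, int]]:
    names = genome.names
    lengths = np.array([genome.length(c) for c in names], dtype=float)
    probs = lengths / lengths.sum()
    out = []
    for _ in range(n):
        ci = int(rng.choice(len(names), p=probs))
        flen = int(feat_len(rng))
        start = int(rng.integers(0, genome.length(names[ci]) - flen + 1))
        out.append((names[ci], start, start + flen))
    return out


def place_features(
    genome: GenomeModel, config: SimulationConfig
) -> tuple[list[GenomicFeature], list[GenomicFeature], PlantedTruth]:
    """Place miRNA loci and imprinted genes; return them with the truth.

    Background positions are uniform per chromosome, chromosomes chosen
    proportionally to length. Each planted cluster drops ``cluster_size`` DE
    miRNAs inside a ``cluster_span`` window; a configured fraction of the
    imprinted genes lands within ``proximity_window`` of a planted cluster.
    """
    rng = _stage_rng(config, 1)
    min_len = min(l for _, l in genome.chromosomes)
    if config.n_planted_clusters > 0 and config.cluster_span >= min_len:
        raise ValueError("cluster_span must be smaller than the shortest chromosome")
    if config.n_clustered > config.n_mirnas_total:
        raise ValueError("more clustered miRNAs requested than total miRNAs")
    n_near = int(round(config.imprinted_near_cluster_fraction * config.n_imprinted))
    if n_near > 0 and config.n_planted_clusters == 0:
        raise ValueError("cannot place genes near clusters: no clusters planted")

    names = genome.names
    lengths = np.array([genome.length(c) for c in names], dtype=float)
    mirna_len = config.mirna_length

    # Planted clusters first (their members take the first ids).
    feasible = lengths > config.cluster_span + mirna_len
    placements: list[tuple[str, int, int]] = []
    cluster_members: list[tuple[str, ...]] = []
    cluster_intervals: list[tuple[str, int, int]] = []
    for k in range(config.n_planted_clusters):
        probs = np.where(feasible, lengths, 0.0)
        if probs.sum() == 0:
            raise ValueError("no chromosome can host a planted cluster")
        ci = int(rng.choice(len(names), p=probs / probs.sum()))
        chrom, clen = names[ci], int(lengths[ci])
        win_start = int(rng.integers(0, clen - config.cluster_span - mirna_len + 1))
        offsets = np.sort(
            rng.integers(0, config.cluster_span + 1, size=config.cluster_size)
        )
        member_ids = []
        for j, off in enumerate(offsets):
            start = win_start + int(off)
            placements.append((chrom, start, start + mirna_len))
            member_ids.append(len(placements) - 1)
        cluster_members.append(tuple(member_ids))  # placeholder indices for now
        lo = min(placements[i][1] for i in member_ids)
        hi = max(placements[i][2] for i in member_ids)
        cluster_intervals.append((chrom, lo, hi))

    n_background = config.n_mirnas_total - config.n_clustered
    placements.extend(
        _uniform_placements(rng, genome, n_background, lambda r: mirna_len)
    )

    width = max(4, len(str(config.n_mirnas_total)))
    mirnas = [
        GenomicFeature(chrom=c, start=s, end=e, name=f"sim-mir-{i:0{width}d}")
        for i, (c, s, e) in enumerate(placements)
    ]
    id_of = [f.name for f in mirnas]
    cluster_member_ids = tuple(
        tuple(id_of[i] for i in members) for members in cluster_members
    )

    # DE set: all clustered miRNAs plus random background miRNAs up to n_de.
    clustered_idx = [i for members in cluster_members for i in members]
    n_extra = config.n_planted_de - len(clustered_idx)
    background_idx = np.arange(config.n_clustered, config.n_mirnas_total)
    extra_idx = (
        sorted(rng.choice(background_idx, size=n_extra, replace=False).tolist())
        if n_extra > 0
        else []
    )
    de_ids = tuple(id_of[i] for i in clustered_idx + list(extra_idx))
    # Planted effects separate both pluripotent groups from the reference, so
    # the same set is DE in each versus-reference contrast and none between
    # the pluripotent groups.
    ref = config.groups[0][0]
    others = [g for g, _, _ in config.groups[1:]]
    de_map = {f"{g}_vs_{ref}": de_ids for g in others}
    if len(others) == 2:
        de_map[f"{others[1]}_vs_{others[0]}"] = ()

    # Imprinted genes: n_near within the window of a planted cluster, rest uniform.
    gene_len = lambda r: int(r.integers(*config.gene_length_range))
    gene_placements: list[tuple[str, int, int]] = []
    for _ in range(n_near):
        k = int(rng.integers(0, len(cluster_intervals)))
        chrom, lo, hi = cluster_intervals[k]
        clen = genome.length(chrom)
        glen = gene_len(rng)
        lo_start = max(0, lo - config.proximity_window)
        hi_start = min(clen - glen, hi + config.proximity_window)
        if hi_start < lo_start:  # tiny chromosome: drop into the cluster itself
            lo_start = hi_start = max(0, min(lo, clen - glen))
        gene_placements.append(
            (chrom, (s := int(rng.integers(lo_start, hi_start + 1))), s + glen)
        )
    gene_placements.extend(
        _uniform_placements(rng, genome, config.n_imprinted - n_near, gene_len)
    )
    gwidth = max(4, len(str(max(1, config.n_imprinted))))
    genes = [
        GenomicFeature(chrom=c, start=s, end=e, name=f"sim-impg-{i:0{gwidth}d}")
        for i, (c, s, e) in enumerate(gene_placements)
    ]
    truth = PlantedTruth(
        de_mirnas=de_map,
        cluster_members=cluster_member_ids,
        cluster_intervals=tuple(cluster_intervals),
        near_genes=tuple(g.name for g in genes[:n_near]),
    )
    return mirnas, genes, truth


def simulate_expression(
    mirnas: list[GenomicFeature],
    truth: PlantedTruth,
    config: SimulationConfig,
) -> ExpressionMatrix:
    """Per-miRNA baseline + group effect + independent Gaussian noise.

    Planted DE miRNAs get an upward shift of ``effect_log2fc`` in every
    non-reference group, so the true group-mean difference versus the
    reference equals ``effect_log2fc`` exactly.
    """
    rng = _stage_rng(config, 2)
    if not config.groups:
        raise ValueError("at least one sample group is required")
    sample_ids, sample_group, sample_line, sample_rep = [], [], [], []
    for gname, n_lines, n_reps in config.groups:
        for line in range(1, n_lines + 1):
            for rep in range(1, n_reps + 1):
                sample_ids.append(f"{gname}_L{line}_R{rep}")
                sample_group.append(gname)
                sample_line.append(f"{gname}_L{line}")
                sample_rep.append(rep)

    ids = [f.name for f in mirnas]
    n, s = len(ids), len(sample_ids)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    de_set = truth.all_de_ids()
    ref = config.groups[0][0]
    effect = np.zeros((n, s))
    de_rows = np.array([i for i, m in enumerate(ids) if m in de_set], dtype=int)
    nonref_cols = np.array([j for j, g in enumerate(sample_group) if g != ref], dtype=int)
    if de_rows.size and nonref_cols.size:
        effect[np.ix_(de_rows, nonref_cols)] = config.effect_log2fc
    values = baseline[:, None] + effect + rng.normal(0.0, config.noise_sd, size=(n, s))

    vdf = pd.DataFrame(values, index=pd.Index(ids, name="mirna_id"), columns=sample_ids)
    sdf = pd.DataFrame(
        {"group": sample_group, "line": sample_line, "replicate": sample_rep},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ExpressionMatrix(values=vdf, samples=sdf)


def simulate_bundle(
    config: SimulationConfig,
) -> tuple[GenomeModel, list[GenomicFeature], list[GenomicFeature], ExpressionMatrix, PlantedTruth]:
    """Run the three generator stages in order under one seed."""
    genome = make_genome(config)
    mirnas, genes, truth = place_features(genome, config)
    expr = simulate_expression(mirnas, truth, config)
    return genome, mirnas, genes, expr, truth


def write_fixture_bundle(
    outdir,
    genome: GenomeModel,
    mirnas: list[GenomicFeature],
    genes: list[GenomicFeature],
    expr: ExpressionMatrix,
    truth: PlantedTruth,
    config: SimulationConfig | None = None,
) -> dict[str, Path]:
    """Write the six interchange files; byte-identical given config + seed."""
    from . import io as _io  # local import: io depends on the domain types

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed} if config is not None else {}
    paths = {
        "mirnas": outdir / "miRNAs.bed",
        "imprinted": outdir / "imprinted.bed",
        "chrom_sizes": outdir / "chrom.sizes",
        "expression": outdir / "expression.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.json",
    }
    _io.write_bed(mirnas, paths["mirnas"], meta=meta)
    _io.write_bed(genes, paths["imprinted"], meta=meta)
    _io.write_chrom_sizes(genome, paths["chrom_sizes"], meta=meta)
    _io.write_expression(expr, paths["expression"], paths["samples"], meta=meta)
    payload = {"truth": truth.to_dict()}
    if config is not None:
        payload["config"] = config.to_dict()
    paths["truth"].write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return paths
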