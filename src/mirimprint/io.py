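"""Readers and writers for the interchange formats.

BED3+ (tab-separated, 0-based half-open, name in column 4), chrom.sizes
(two-column TSV), expression matrix + sample sheet TSVs, and the JSON result
files. Every writer emits a provenance header (``#`` comment lines with
package version, parameters, and seed) that every reader skips, so files
round-trip losslessly and identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__
from .clustering import ClusterRegion
from .de import DESelection, ExpressionMatrix, ContrastResult
from .enrichment import EnrichmentResult
from .genome import GenomeModel, GenomicFeature

__all__ = [
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_expression",
    "write_expression",
    "write_de_results",
    "write_de_sets",
    "read_de_sets",
    "write_clusters_tsv",
    "read_clusters_tsv",
    "write_clusters_bed",
    "write_enrichment",
    "read_enrichment",
]


def _header_lines(meta: dict | None) -> list[str]:
    lines = [f"# mirimprint v{__version__}"]
    for key in sorted(meta or {}):
        lines.append(f"# {key}={meta[key]}")
    return lines


def _is_comment(line: str) -> bool:
    return line.startswith("#") or line.startswith("track ") or not line.strip()


def read_bed(path) -> list[GenomicFeature]:
    """Parse BED3+ into features; malformed lines raise with their number."""
    feats: list[GenomicFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_comment(line):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if start < 0 or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            name = parts[3] if len(parts) > 3 and parts[3] else f"feature_{lineno}"
            feats.append(GenomicFeature(chrom=chrom, start=start, end=end, name=name))
    return feats


def write_bed(features: list[GenomicFeature], path, meta: dict | None = None) -> None:
    lines = _header_lines(meta)
    for f in features:
        lines.append(f"{f.chrom}\t{f.start}\t{f.end}\t{f.name}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_chrom_sizes(path) -> GenomeModel:
    chroms: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_comment(line):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'name<TAB>length'")
            try:
                chroms.append((parts[0], int(parts[1])))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer length") from None
    return GenomeModel(chromosomes=tuple(chroms))


def write_chrom_sizes(genome: GenomeModel, path, meta: dict | None = None) -> None:
    lines = _header_lines(meta)
    lines.extend(f"{name}\t{length}" for name, length in genome.chromosomes)
    Path(path).write_text("\n".join(lines) + "\n")


def read_expression(expr_path, samples_path) -> ExpressionMatrix:
    """Load the matrix + sample sheet; validation errors name the culprit."""
    values = pd.read_csv(expr_path, sep="\t", comment="#", index_col=0)
    if values.index.has_duplicates:
        dupes = values.index[values.index.duplicated()].unique().tolist()
        raise ValueError(f"{expr_path}: duplicate miRNA ids: {dupes[:5]}")
    for col in values.columns:
        bad = values.index[pd.to_numeric(values[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(
                f"{expr_path}: non-numeric value at row {bad[0]!r}, column {col!r}"
            )
    values = values.astype(float)
    samples = pd.read_csv(samples_path, sep="\t", comment="#", index_col=0)
    missing = [c for c in values.columns if c not in samples.index]
    if missing:
        raise ValueError(f"{samples_path}: no metadata for sample(s) {missing}")
    return ExpressionMatrix(values=values, samples=samples)


def write_expression(
    expr: ExpressionMatrix, expr_path, samples_path, meta: dict | None = None
) -> None:
    header = "\n".join(_header_lines(meta)) + "\n"
    with open(expr_path, "w") as fh:
        fh.write(header)
        expr.values.to_csv(fh, sep="\t", float_format="%.6f", lineterminator="\n")
    with open(samples_path, "w") as fh:
        fh.write(header)
        expr.samples.to_csv(fh, sep="\t", lineterminator="\n")


def write_de_results(
    results: list[ContrastResult], path, meta: dict | None = None
) -> None:
    """One row per miRNA per contrast: id, contrast, log2FC, t, p, fdr."""
    header = "\n".join(_header_lines(meta)) + "\n"
    frames = []
    for r in results:
        t = r.table.copy()
        t.insert(0, "contrast", r.label)
        t.index.name = "mirna_id"
        frames.append(t.reset_index())
    out = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(header)
        out.to_csv(fh, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def _json_dump(payload: dict, path, meta: dict | None = None) -> None:
    payload = {"_provenance": {"version": __version__, **(meta or {})}, **payload}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_de_sets(selection: DESelection, path, meta: dict | None = None) -> None:
    _json_dump(selection.to_dict(), path, meta)


def read_de_sets(path) -> DESelection:
    return DESelection.from_dict(json.loads(Path(path).read_text()))


_CLUSTER_COLS = [
    "cluster_id", "chrom", "start", "end", "n_members", "max_gap",
    "m_chrom", "chrom_length", "p_value", "members",
]


def write_clusters_tsv(
    clusters: list[ClusterRegion], path, meta: dict | None = None
) -> None:
    lines = _header_lines(meta)
    lines.append("\t".join(_CLUSTER_COLS))
    for c in clusters:
        lines.append(
            "\t".join(
                [
                    c.name, c.chrom, str(c.start), str(c.end), str(c.n_members),
                    str(c.max_gap), str(c.n_chrom_mirnas), str(c.chrom_length),
                    f"{c.p_value:.6g}", ",".join(c.members),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_clusters_tsv(path) -> list[ClusterRegion]:
    clusters: list[ClusterRegion] = []
    with open(path) as fh:
        rows = [l for l in fh if not _is_comment(l)]
    header = rows[0].rstrip("\n").split("\t")
    if header != _CLUSTER_COLS:
        raise ValueError(f"{path}: unexpected cluster table columns {header}")
    for row in rows[1:]:
        f = dict(zip(header, row.rstrip("\n").split("\t")))
        clusters.append(
            ClusterRegion(
                chrom=f["chrom"],
                start=int(f["start"]),
                end=int(f["end"]),
                members=tuple(f["members"].split(",")),
                n_members=int(f["n_members"]),
                max_gap=int(f["max_gap"]),
                n_chrom_mirnas=int(f["m_chrom"]),
                chrom_length=int(f["chrom_length"]),
                p_value=float(f["p_value"]),
                name=f["cluster_id"],
            )
        )
    return clusters


def write_clusters_bed(
    clusters: list[ClusterRegion], path, meta: dict | None = None
) -> None:
    """BED6 with score = round(−10·log10 P) capped at 1000 for browser triage."""
    import math

    lines = _header_lines(meta)
    for c in clusters:
        score = 1000 if c.p_value <= 0 else min(1000, round(-10 * math.log10(c.p_value)))
        lines.append(
            f"{c.chrom}\t{c.start}\t{c.end}\t{c.name}\t{max(0, score)}\t."
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_enrichment(result: EnrichmentResult, path, meta: dict | None = None) -> None:
    _json_dump(result.to_dict(), path, meta)


def read_enrichment(path) -> EnrichmentResult:
    return EnrichmentResult.from_dict(json.loads(Path(path).read_text()))
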