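"""Genomic coordinate primitives shared by every pipeline stage.

All coordinates are 0-based half-open (BED convention). A miRNA locus is an
interval like any other feature; wherever a single "position" is needed (the
positional clustering), the interval's start coordinate is used.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GenomeModel:
    """An ordered set of chromosomes with lengths in bp.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length)`` pairs. Names must be unique and lengths
        strictly positive.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        chroms = tuple((str(n), int(l)) for n, l in self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        if not chroms:
            raise ValueError("genome must contain at least one chromosome")
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in chroms:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths


@dataclass(frozen=True, order=True)
class GenomicFeature:
    """A named half-open interval ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int
    name: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"feature {self.name!r}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


# Domain aliases: a profiled miRNA locus and an imprinted gene are both plain
# named intervals; the distinction is which file they came from.
MiRNALocus = GenomicFeature
ImprintedGene = GenomicFeature
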