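import numpy as np
import pandas as pd
import pytest

from mirimprint import ExpressionMatrix, GenomeModel, GenomicFeature, SimulationConfig


@pytest.fixture
def one_chrom_genome() -> GenomeModel:
    return GenomeModel(chromosomes=(("chr1", 100_000_000),))


@pytest.fixture
def small_config() -> SimulationConfig:
    """A fast, small synthetic design: one planted cluster, modest counts."""
    return SimulationConfig(
        n_mirnas_total=120,
        n_planted_clusters=1,
        cluster_span=50_000,
        cluster_size=5,
        n_imprinted=30,
        imprinted_near_cluster_fraction=0.2,
        de_fraction=0.2,
        chromosomes=(("chr1", 100_000_000), ("chr2", 80_000_000)),
        seed=11,
    )


def toy_expression(values: np.ndarray, groups: list[str]) -> ExpressionMatrix:
    """Wrap a raw matrix with minimal metadata; columns named g_i."""
    cols = [f"{g}_{i}" for i, g in enumerate(groups)]
    vdf = pd.DataFrame(
        values,
        index=[f"m{i:03d}" for i in range(values.shape[0])],
        columns=cols,
    )
    sdf = pd.DataFrame(
        {"group": groups, "line": groups, "replicate": list(range(len(groups)))},
        index=vdf.columns,
    )
    return ExpressionMatrix(values=vdf, samples=sdf)


def point_loci(positions, chrom="chr1", prefix="mir", length=1) -> list[GenomicFeature]:
    return [
        GenomicFeature(chrom=chrom, start=int(p), end=int(p) + length, name=f"{prefix}{i:04d}")
        for i, p in enumerate(positions)
    ]
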