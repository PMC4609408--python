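"""Moderated two-group differential expression for log2 microarray intensities.

The model is the two-group special case of the empirical-Bayes linear-model
framework standard for microarrays: per-miRNA pooled residual variances s²
with d degrees of freedom are shrunk towards a prior (d0, s0²) fitted by the
method of moments on log residual variances, giving

    s̃² = (d0·s0² + d·s²) / (d0 + d)
    t  = (mean_A − mean_B) / sqrt(s̃² · (1/n_A + 1/n_B))

with p-values from a t distribution on d0 + d degrees of freedom (capped at
the total pooled residual df across miRNAs). Contrasts are combined with
set algebra: miRNAs significant versus the reference cell type (fibroblasts)
in both pluripotent cell types form the "both" set, optionally restricted by
a per-contrast fold-change filter; miRNAs significant in exactly one of the
two contrasts form the "discordant" set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "ContrastResult",
    "DESelection",
    "fit_contrast",
    "bh_fdr",
    "select_de",
    "moments_prior",
]


@dataclass
class ExpressionMatrix:
    """Log2 intensities (miRNA × sample) with sample metadata.

    ``values`` is indexed by miRNA id with one column per sample id;
    ``samples`` is indexed by sample id with columns ``group``, ``line``,
    ``replicate``. Every matrix column must have a metadata row.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate miRNA ids: {dupes[:5]}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        missing = [c for c in self.values.columns if c not in self.samples.index]
        if missing:
            raise ValueError(f"samples missing metadata: {missing}")
        if "group" not in self.samples.columns:
            raise ValueError("sample metadata must have a 'group' column")
        if self.samples.loc[list(self.values.columns), "group"].isna().any():
            raise ValueError("every sample must have a group")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.values.columns:
            seen.setdefault(str(self.samples.loc[c, "group"]), None)
        return list(seen)

    def group_columns(self, group: str) -> list[str]:
        cols = [c for c in self.values.columns if self.samples.loc[c, "group"] == group]
        if not cols:
            raise ValueError(f"group {group!r} not present in sample metadata")
        return cols


@dataclass
class ContrastResult:
    """Per-miRNA statistics for one pairwise contrast (A minus B)."""

    group_a: str
    group_b: str
    table: pd.DataFrame  # columns: log2_fc, t, p_value, fdr
    prior_df: float
    prior_var: float
    residual_df: float

    @property
    def label(self) -> str:
        return f"{self.group_a}_vs_{self.group_b}"

    def significant(self, fdr_cutoff: float) -> frozenset[str]:
        return frozenset(self.table.index[self.table["fdr"] <= fdr_cutoff])


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse requires x > 0")
    if x > 1e7:  # trigamma(y) ~ 1/y near 0
        return 1.0 / math.sqrt(x)
    if x < 1e-6:  # trigamma(y) ~ 1/y for large y
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(60):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def moments_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Fit the variance prior (d0, s0²) by moments on log sample variances.

    The scaled-inverse-chi-square prior implies log(s²) is a shifted log-F
    variate; matching its mean and variance yields the prior df and scale.
    Returns ``(inf, s0²)`` when the observed spread of log variances is no
    larger than expected from sampling noise alone. Non-positive variances
    (flat miRNAs) are excluded from the fit.
    """
    s2 = np.asarray(s2, dtype=float)
    if df <= 0:
        raise ValueError("residual df must be positive")
    ok = s2 > 0
    if not np.any(ok):
        # Fully degenerate matrix (every miRNA flat): a point prior at zero.
        return math.inf, 0.0
    z = np.log(s2[ok])
    e = z - float(special.digamma(df / 2.0)) + math.log(df / 2.0)
    emean = float(np.mean(e))
    if e.size < 2:
        return math.inf, float(math.exp(emean))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return math.inf, float(math.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0 = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return d0, s0


def fit_contrast(
    expr: ExpressionMatrix,
    group_a: str,
    group_b: str,
    *,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> ContrastResult:
    """Moderated t contrast of ``group_a`` minus ``group_b``.

    ``prior_df`` / ``prior_var`` override the moment-estimated prior (useful
    to force the ordinary pooled t with ``prior_df=0`` or the fully shrunken
    z-like statistic with ``prior_df=inf``).
    """
    cols_a = expr.group_columns(group_a)
    cols_b = expr.group_columns(group_b)
    na, nb = len(cols_a), len(cols_b)
    if na < 2 or nb < 2:
        raise ValueError(
            f"contrast {group_a} vs {group_b} needs >=2 samples per group "
            f"(got {na}, {nb})"
        )
    a = expr.values[cols_a].to_numpy(dtype=float)
    b = expr.values[cols_b].to_numpy(dtype=float)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    d = float(na + nb - 2)
    s2 = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / d

    d0, s0 = prior_df, prior_var
    if d0 is None or (s0 is None and d0 != 0):
        est_d0, est_s0 = moments_prior(s2, d)
        if d0 is None:
            d0 = est_d0
        if s0 is None:
            s0 = est_s0
    if d0 < 0 or (s0 is not None and s0 < 0):
        raise ValueError("prior df and variance must be non-negative")

    if math.isinf(d0):
        s2_post = np.full_like(s2, s0)
    elif d0 == 0:
        s2_post = s2
    else:
        s2_post = (d0 * s0 + d * s2) / (d0 + d)

    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), np.where(lfc == 0, 0.0, np.inf * np.sign(lfc)))

    # Cap total df at the pooled residual df across miRNAs, as the shrinkage
    # cannot add more information than the experiment contains.
    df_total = d0 + d
    if math.isfinite(df_total):
        df_total = min(df_total, d * len(s2))
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    else:
        p = 2.0 * stats.norm.sf(np.abs(t))
    p = np.where(np.isinf(t), 0.0, p)
    p = np.clip(p, 0.0, 1.0)

    table = pd.DataFrame(
        {"log2_fc": lfc, "t": t, "p_value": p, "fdr": bh_fdr(p)},
        index=expr.values.index,
    )
    return ContrastResult(
        group_a=group_a,
        group_b=group_b,
        table=table,
        prior_df=float(d0),
        prior_var=float(s0) if s0 is not None else float("nan"),
        residual_df=d,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DESelection:
    """Significant sets per contrast plus the combined pluripotency sets.

    ``both`` holds miRNAs significant versus the reference group in both
    non-reference contrasts; ``both_min_fold`` additionally requires the
    fold-change magnitude in each of those two contrasts; ``discordant``
    holds miRNAs significant in exactly one of them.
    """

    per_contrast: dict[str, frozenset[str]]
    both: frozenset[str]
    both_min_fold: frozenset[str]
    discordant: frozenset[str]
    reference: str
    fdr_cutoff: float
    fold_cutoff: float
    vs_reference_labels: tuple[str, str] = field(default=("", ""))

    @property
    def union_vs_reference(self) -> frozenset[str]:
        a, b = self.vs_reference_labels
        return self.per_contrast[a] | self.per_contrast[b]

    @property
    def union_all(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for s in self.per_contrast.values():
            out |= s
        return out

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "fdr_cutoff": self.fdr_cutoff,
            "fold_cutoff": self.fold_cutoff,
            "vs_reference_labels": list(self.vs_reference_labels),
            "per_contrast": {k: sorted(v) for k, v in self.per_contrast.items()},
            "both": sorted(self.both),
            "both_min_fold": sorted(self.both_min_fold),
            "discordant": sorted(self.discordant),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DESelection":
        return cls(
            per_contrast={k: frozenset(v) for k, v in d["per_contrast"].items()},
            both=frozenset(d["both"]),
            both_min_fold=frozenset(d["both_min_fold"]),
            discordant=frozenset(d["discordant"]),
            reference=d["reference"],
            fdr_cutoff=float(d["fdr_cutoff"]),
            fold_cutoff=float(d["fold_cutoff"]),
            vs_reference_labels=tuple(d["vs_reference_labels"]),
        )


def select_de(
    results: list[ContrastResult],
    fdr_cutoff: float = 0.05,
    fold_cutoff: float = 2.0,
    reference: str = "NHDF",
) -> DESelection:
    """Combine the three pairwise contrasts into the pluripotency DE sets.

    Requires two contrasts against the reference group and one contrast
    between the two non-reference groups. The fold filter keeps members of
    ``both`` whose |log2 fold change| is at least log2(fold_cutoff) in each
    of the two versus-reference contrasts.
    """
    if fold_cutoff < 1:
        raise ValueError("fold_cutoff must be >= 1")
    vs_ref = [r for r in results if reference in (r.group_a, r.group_b)]
    other = [r for r in results if reference not in (r.group_a, r.group_b)]
    if len(vs_ref) != 2 or len(other) != 1:
        raise ValueError(
            "need exactly two contrasts against the reference group "
            f"{reference!r} and one between the remaining groups; got "
            f"{[r.label for r in results]}"
        )
    sig = {r.label: r.significant(fdr_cutoff) for r in results}
    r1, r2 = vs_ref
    both = sig[r1.label] & sig[r2.label]
    log2_min = math.log2(fold_cutoff)
    fold_ok = frozenset(
        m
        for m in both
        if abs(r1.table.at[m, "log2_fc"]) >= log2_min
        and abs(r2.table.at[m, "log2_fc"]) >= log2_min
    )
    discordant = sig[r1.label] ^ sig[r2.label]
    return DESelection(
        per_contrast=sig,
        both=frozenset(both),
        both_min_fold=fold_ok,
        discordant=frozenset(discordant),
        reference=reference,
        fdr_cutoff=fdr_cutoff,
        fold_cutoff=fold_cutoff,
        vs_reference_labels=(r1.label, r2.label),
    )
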