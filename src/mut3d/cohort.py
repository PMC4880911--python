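"""Cohort-level statistics over per-gene test results.

Once genes are called, three downstream questions recur: are known cancer
genes (oncogenes, tumor suppressors, census genes) over-represented among
the significant set (Fisher's exact test); do gene classes differ in
mutated-sample frequency or in clustering tightness (Wilcoxon rank-sum);
and how tight is the mutation clustering once gene size is accounted for
(average distance adjusted for coding-sequence length).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "fisher_enrichment",
    "wilcoxon_ranksum",
    "length_adjusted_distance",
    "read_annotations",
]


@dataclass(frozen=True)
class EnrichmentResult:
    odds_ratio: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]


def fisher_enrichment(
    significant_genes: set, annotated_genes: set, universe: set
) -> EnrichmentResult:
    """Two-sided Fisher's exact test for annotation enrichment.

    The 2x2 table is [[sig&anno, sig-anno], [nonsig&anno, nonsig-anno]]
    over the tested-gene universe; the reported odds ratio is the
    cross-product ratio ad/bc (inf when bc = 0 and ad > 0).
    """
    if not universe:
        raise ValueError("empty universe")
    if not annotated_genes <= universe or not significant_genes <= universe:
        raise ValueError("significant and annotated sets must lie in the universe")
    a = len(significant_genes & annotated_genes)
    b = len(significant_genes - annotated_genes)
    nonsig = universe - significant_genes
    c = len(nonsig & annotated_genes)
    d = len(nonsig - annotated_genes)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        oddsr = float("inf") if a * d > 0 else float("nan")
    else:
        oddsr = (a * d) / (b * c)
    return EnrichmentResult(odds_ratio=oddsr, p_value=float(p), table=((a, b), (c, d)))


def wilcoxon_ranksum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when both samples are small (min size <= 8) and
    tie-free; otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return float(min(res.pvalue, 1.0))


def length_adjusted_distance(
    distances: Sequence[float],
    cds_lengths: Sequence[float],
    method: str = "residual",
) -> np.ndarray:
    """Average distances adjusted for coding-sequence length.

    Bigger proteins have bigger structures, so raw average distances are
    not comparable across genes. Two adjustments are offered:

    - ``"residual"`` (default): residuals of an ordinary least-squares fit
      of distance on CDS length across the cohort. With a constant-length
      cohort the fit degenerates to the intercept and the residuals are
      the centered distances.
    - ``"ratio"``: distance divided by cds_length**(1/3), the isometric
      scaling of a linear dimension with chain volume.
    """
    d = np.asarray(distances, dtype=float)
    L = np.asarray(cds_lengths, dtype=float)
    if d.size != L.size:
        raise ValueError("distances and cds_lengths must have equal length")
    if d.size < 3:
        raise ValueError("need at least 3 genes to adjust for length")
    if np.any(L <= 0):
        raise ValueError("cds_lengths must be positive")
    if method == "ratio":
        return d / np.cbrt(L)
    if method != "residual":
        raise ValueError(f"unknown method: {method!r}")
    X = np.column_stack([np.ones_like(L), L])
    beta, *_ = np.linalg.lstsq(X, d, rcond=None)
    return d - X @ beta


def read_annotations(source, gene_column: str = "gene", class_column: str = "class"
                     ) -> dict[str, set[str]]:
    """Read a (gene, class) TSV into {class: set of genes}.

    Classes are free-form labels, typically ``oncogene``, ``tsg`` and
    ``census``; a gene may appear under several classes.
    """
    df = pd.read_csv(source, sep="\t", dtype=str)
    out: dict[str, set[str]] = {}
    for g, c in zip(df[gene_column], df[class_column]):
        out.setdefault(str(c), set()).add(str(g))
    return out
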