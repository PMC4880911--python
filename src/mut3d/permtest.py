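"""The permutation test for skewed mutation distributions.

Given a gene with n mutations placed on a protein structure, the observed
statistic is the average pairwise Euclidean distance between the n mutated
residues. Under the null hypothesis that mutations fall uniformly at random
on the structure, the null distribution of that statistic is estimated by
Monte Carlo: n positions are drawn uniformly from the residues with
coordinates, the simulated average distance is computed, and this is
repeated m times. The Monte-Carlo p-value uses the add-one estimator

    p = (#{simulated <= observed} + 1) / (m + 1),

which is never zero and is a valid p-value for any m. Ties between
simulated and observed distances count toward the numerator (conservative).

A two-stage adaptive scheme keeps the cost manageable across thousands of
genes: every gene is first tested with m = 10^4 draws; genes with a
stage-1 p-value <= 0.01 are re-tested with m = 10^6 fresh draws to resolve
small p-values accurately.

The same construction on the primary sequence — distance = absolute codon
difference, universe = codons 1..CDS length — is the 1D control test.

Null draws are made WITH replacement by default: the observed data count
recurrent codons with multiplicity, so the matching null of n independent
uniform hits must allow coincident positions. A without-replacement mode
exists for sensitivity analysis.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .structures import ProteinStructure

__all__ = [
    "DistanceObservation",
    "PermutationResult",
    "GeneCall",
    "avg_pairwise_distance_3d",
    "avg_pairwise_distance_1d",
    "permutation_pvalue",
    "exact_pvalue",
    "adaptive_pvalue",
    "select_best_structure",
    "bh_fdr",
    "call_genes",
    "derive_seed",
]

_CHUNK = 200_000  # Monte-Carlo draws per vectorized block


@dataclass(frozen=True)
class DistanceObservation:
    """Observed average pairwise distance for one gene on one structure."""

    gene: str
    structure_id: str
    n: int
    observed_avg_distance: float
    dimension: str = "3D"  # "3D" (Angstroms) or "1D" (codons)


@dataclass(frozen=True)
class PermutationResult:
    """Monte-Carlo test outcome for one (gene, structure) pair."""

    observation: DistanceObservation
    m: int
    k: int
    p_value: float
    seed: int
    stage: int = 1
    stage1_p: Optional[float] = None

    def __post_init__(self):
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p-value must lie in (0, 1]")


@dataclass(frozen=True)
class GeneCall:
    """Per-gene verdict after FDR correction and frequency filtering."""

    gene: str
    cancer_type: str
    best_structure_id: str
    p_value: float
    q_value: float
    sample_freq: float
    n: int
    significant: bool
    dimension: str = "3D"


def avg_pairwise_distance_3d(coords: Union[np.ndarray, Sequence]) -> float:
    """Mean Euclidean distance over all unordered pairs of points.

    Duplicated points (mutation hotspots) contribute zero-distance pairs.
    """
    pts = np.asarray(coords, dtype=float).reshape(-1, 3)
    if len(pts) < 2:
        raise ValueError("undefined statistic: need at least 2 mutations")
    return float(pdist(pts).mean())


def avg_pairwise_distance_1d(positions: Sequence[int]) -> float:
    """Mean absolute codon-index difference over all unordered pairs."""
    x = np.asarray(positions, dtype=float)
    if x.size < 2:
        raise ValueError("undefined statistic: need at least 2 mutations")
    return float(pdist(x[:, None]).mean())


def derive_seed(base_seed: int, *tokens) -> int:
    """Stable 64-bit stream seed from a base seed plus context tokens.

    Gene-level results must not depend on scheduling order, so every
    (cancer type, gene, structure, stage, dimension) combination gets its
    own deterministic stream derived by hashing.
    """
    h = hashlib.sha256(repr((int(base_seed),) + tokens).encode()).digest()
    return int.from_bytes(h[:8], "little")


def _universe(
    universe: Union[ProteinStructure, np.ndarray, int], dimension: str
) -> tuple[np.ndarray, int]:
    """Resolve the sampling universe to (per-position values, size).

    3D: (U, 3) coordinate array of residues eligible for null sampling.
    1D: codon indices 1..L as a (L, 1) column.
    """
    if dimension == "3D":
        if isinstance(universe, ProteinStructure):
            pts = universe.coordinates()
        else:
            pts = np.asarray(universe, dtype=float).reshape(-1, 3)
        return pts, len(pts)
    if dimension == "1D":
        if not isinstance(universe, (int, np.integer)):
            raise TypeError("1D universe must be the CDS length in codons")
        pts = np.arange(1, int(universe) + 1, dtype=float)[:, None]
        return pts, int(universe)
    raise ValueError(f"unknown dimension: {dimension!r}")


def _simulated_distances(
    dmat: np.ndarray,
    universe_size: int,
    n: int,
    m: int,
    rng: np.random.Generator,
    replacement: bool,
) -> np.ndarray:
    """m simulated average pairwise distances for draws of size n."""
    pairs = [(a, b) for a in range(n) for b in range(a + 1, n)]
    out = np.empty(m)
    done = 0
    # without-replacement index generation is memory-heavier; smaller chunks
    chunk = _CHUNK if replacement else max(1, _CHUNK // max(universe_size // 8, 1))
    while done < m:
        c = min(chunk, m - done)
        if replacement:
            idx = rng.integers(0, universe_size, size=(c, n))
        else:
            keys = rng.random((c, universe_size))
            idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        acc = np.zeros(c)
        for a, b in pairs:
            acc += dmat[idx[:, a], idx[:, b]]
        out[done : done + c] = acc / len(pairs)
        done += c
    return out


def permutation_pvalue(
    universe: Union[ProteinStructure, np.ndarray, int],
    n: int,
    observed: float,
    m: int,
    seed: int,
    dimension: str = "3D",
    replacement: bool = True,
    gene: str = "",
    structure_id: str = "",
    stage: int = 1,
) -> PermutationResult:
    """Monte-Carlo p-value for an observed average pairwise distance.

    Parameters
    ----------
    universe
        For 3D: a :class:`ProteinStructure` or (U, 3) coordinate array —
        the residues eligible for null sampling. For 1D: the CDS length L,
        giving the codon universe 1..L.
    n
        Number of mutations; draws of this size are simulated.
    observed
        Observed average pairwise distance (Angstroms or codons).
    m
        Number of Monte-Carlo draws.
    seed
        Seed for the draw stream; identical seeds reproduce results.
    replacement
        Draw positions with replacement (default) or without.
    """
    pts, size = _universe(universe, dimension)
    if size < 2:
        raise ValueError("sampling universe must contain at least 2 positions")
    if n < 2:
        raise ValueError("undefined statistic: need at least 2 mutations")
    if not replacement and n > size:
        raise ValueError("cannot draw more positions than the universe holds")
    dmat = squareform(pdist(pts))
    rng = np.random.default_rng(seed)
    sims = _simulated_distances(dmat, size, n, m, rng, replacement)
    k = int(np.count_nonzero(sims <= observed))
    obs = DistanceObservation(
        gene=gene,
        structure_id=structure_id,
        n=n,
        observed_avg_distance=float(observed),
        dimension=dimension,
    )
    return PermutationResult(
        observation=obs, m=m, k=k, p_value=(k + 1) / (m + 1), seed=seed, stage=stage
    )


def exact_pvalue(
    universe: Union[ProteinStructure, np.ndarray, int],
    n: int,
    observed: float,
    dimension: str = "3D",
    max_draws: int = 10_000_000,
) -> float:
    """Exact null probability P(simulated average distance <= observed).

    Full enumeration of all universe_size**n ordered with-replacement
    draws — the limit of the Monte-Carlo estimator as m grows. Usable only
    on small instances; guards against combinatorial explosion.
    """
    pts, size = _universe(universe, dimension)
    if size < 2:
        raise ValueError("sampling universe must contain at least 2 positions")
    if n < 2:
        raise ValueError("undefined statistic: need at least 2 mutations")
    total = size**n
    if total > max_draws:
        raise ValueError(f"enumeration of {total} draws exceeds limit {max_draws}")
    dmat = squareform(pdist(pts))
    grids = np.meshgrid(*([np.arange(size)] * n), indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)
    acc = np.zeros(total)
    npairs = 0
    for a in range(n):
        for b in range(a + 1, n):
            acc += dmat[idx[:, a], idx[:, b]]
            npairs += 1
    sims = acc / npairs
    # tiny relative slack: the enumerated and observed statistics may come
    # from different float summation orders
    tol = 1e-9 * (1.0 + abs(observed))
    return float(np.count_nonzero(sims <= observed + tol) / total)


def adaptive_pvalue(
    universe: Union[ProteinStructure, np.ndarray, int],
    n: int,
    observed: float,
    base_seed: int,
    dimension: str = "3D",
    m1: int = 10_000,
    m2: int = 1_000_000,
    escalate_p: float = 0.01,
    replacement: bool = True,
    gene: str = "",
    structure_id: str = "",
    cancer_type: str = "",
) -> PermutationResult:
    """Two-stage adaptive Monte-Carlo p-value.

    Stage 1 uses ``m1`` draws; if its p-value is <= ``escalate_p``
    (inclusive), the gene is re-tested from scratch with ``m2`` draws on a
    fresh deterministic stream and the stage-2 result is reported with the
    stage-1 p-value attached. Otherwise the stage-1 result stands.
    """
    seed1 = derive_seed(base_seed, cancer_type, gene, structure_id, dimension, 1)
    res1 = permutation_pvalue(
        universe, n, observed, m1, seed1, dimension, replacement,
        gene=gene, structure_id=structure_id, stage=1,
    )
    if res1.p_value > escalate_p:
        return res1
    seed2 = derive_seed(base_seed, cancer_type, gene, structure_id, dimension, 2)
    res2 = permutation_pvalue(
        universe, n, observed, m2, seed2, dimension, replacement,
        gene=gene, structure_id=structure_id, stage=2,
    )
    return replace(res2, stage1_p=res1.p_value)


def select_best_structure(results: Sequence[PermutationResult]) -> PermutationResult:
    """Pick the representative result for a gene with several structures.

    The structure with the lowest p-value wins; ties prefer the larger
    mutation count n, then the lexicographically smallest structure id.
    """
    if not results:
        raise ValueError("no permutation results to select from")
    return min(
        results,
        key=lambda r: (r.p_value, -r.observation.n, r.observation.structure_id),
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_genes(
    results: Sequence[PermutationResult],
    frequencies: dict[str, float],
    cancer_type: str = "",
    q_threshold: float = 0.1,
    freq_threshold: float = 0.03,
    min_n: int = 3,
) -> list[GeneCall]:
    """FDR-correct one cancer type's gene results and flag significance.

    The BH family is exactly the set of tested genes passed in (one result
    per gene, after structure selection). A gene is significant when its
    q-value is <= ``q_threshold`` (inclusive) AND its mutated-sample
    frequency is strictly above ``freq_threshold``. Genes with fewer than
    ``min_n`` mutations must not be tested at all and are rejected here.
    """
    results = [r for r in results]
    for r in results:
        if r.observation.n < min_n:
            raise ValueError(
                f"gene {r.observation.gene!r} has n={r.observation.n} < {min_n}; "
                "it should not have been tested"
            )
    if not results:
        return []
    q = bh_fdr([r.p_value for r in results])
    calls = []
    for r, qv in zip(results, q):
        freq = frequencies.get(r.observation.gene, 0.0)
        calls.append(
            GeneCall(
                gene=r.observation.gene,
                cancer_type=cancer_type,
                best_structure_id=r.observation.structure_id,
                p_value=r.p_value,
                q_value=float(qv),
                sample_freq=freq,
                n=r.observation.n,
                significant=bool(qv <= q_threshold and freq > freq_threshold),
                dimension=r.observation.dimension,
            )
        )
    return calls
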