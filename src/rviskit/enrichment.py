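"""Gene-set enrichment over the constraint ranking.

Genes are ranked ascending by RVIS (most constrained first).  Two
complementary tests:

* an unweighted Kolmogorov–Smirnov running-sum enrichment score — each
  set member ("hit") adds 1/Nh, each non-member subtracts 1/(N−Nh); the
  enrichment score (ES) is the deviation of maximum absolute value,
  positive when members cluster toward the constrained top — with a
  permutation null built from random gene sets of the same size;
* a hypergeometric over-representation test of the set within the
  top-2% most constrained tail (tail size = floor(N × fraction)).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps

from .stats import GeneSet


@dataclass(frozen=True)
class RankedGenome:
    """Genes ordered ascending by score; ties broken by gene label."""

    genes: tuple
    scores: tuple

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    es: float
    p_value: float
    n_permutations: int
    seed: int
    leading_edge_size: int


@dataclass(frozen=True)
class OverrepResult:
    set_name: str
    universe_n: int
    tail_n: int
    set_k_in_universe: int
    overlap_k: int
    p_value: float


def rank_genes(scores: pd.Series) -> RankedGenome:
    """Rank ascending by score, most constrained (most negative) first.

    Ties are broken by lexicographic gene label so the ranking is
    deterministic.  ``scores`` is a gene-indexed Series of finite
    values (outliers already excluded).
    """
    s = scores.dropna()
    if len(s) == 0:
        raise ValueError("empty score table; nothing to rank")
    if not np.all(np.isfinite(s.to_numpy(float))):
        raise ValueError("scores must be finite")
    df = pd.DataFrame({"gene": s.index.astype(str), "score": s.to_numpy(float)})
    df = df.sort_values(["score", "gene"], kind="mergesort", ignore_index=True)
    return RankedGenome(tuple(df["gene"]), tuple(df["score"]))


def _hit_mask(ranked: RankedGenome, gene_set: GeneSet) -> np.ndarray:
    members = set(gene_set.members)
    mask = np.fromiter(
        (g in members for g in ranked.genes), bool, count=len(ranked)
    )
    nh = int(mask.sum())
    if nh == 0:
        raise ValueError(
            f"gene set {gene_set.name!r} is disjoint from the ranked genome"
        )
    if nh == len(ranked):
        raise ValueError(
            f"gene set {gene_set.name!r} covers the entire ranked genome"
        )
    dropped = len(members) - nh
    if dropped > 0:
        warnings.warn(
            f"gene set {gene_set.name!r}: {dropped} member(s) absent from the "
            "ranked genome were dropped",
            stacklevel=3,
        )
    return mask


def _es_from_mask(mask: np.ndarray) -> tuple[float, int]:
    """Signed extremum of the running sum plus its 1-based position."""
    n = mask.size
    nh = int(mask.sum())
    steps = np.where(mask, 1.0 / nh, -1.0 / (n - nh))
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), i + 1


def ks_enrichment_score(ranked: RankedGenome, gene_set: GeneSet) -> float:
    """Unweighted KS enrichment score in [-1, 1].

    Positive: members cluster toward the constrained top of the ranking;
    negative: toward the tolerant bottom.
    """
    es, _ = _es_from_mask(_hit_mask(ranked, gene_set))
    return es


def permutation_pvalue(
    ranked: RankedGenome,
    gene_set: GeneSet,
    n_perm: int = 10_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Permutation p-value for |ES| with a +1 correction.

    The null redraws random gene sets of the same effective size from
    the ranked genome (equivalent to permuting gene labels);
    p = (1 + #{|ES_null| >= |ES_obs|}) / (n_perm + 1), so p >= 1/(n_perm+1).
    Deterministic for a fixed seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    mask = _hit_mask(ranked, gene_set)
    n, nh = mask.size, int(mask.sum())
    es_obs, peak = _es_from_mask(mask)
    leading_edge = int(mask[:peak].sum()) if es_obs >= 0 else int(
        mask[peak - 1:].sum()
    )
    rng = np.random.default_rng(seed)
    exceed = 0
    null_mask = np.zeros(n, bool)
    for _ in range(n_perm):
        null_mask[:] = False
        null_mask[rng.choice(n, size=nh, replace=False)] = True
        es_null, _ = _es_from_mask(null_mask)
        if abs(es_null) >= abs(es_obs) - 1e-12:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return EnrichmentResult(
        set_name=gene_set.name,
        es=es_obs,
        p_value=p,
        n_permutations=n_perm,
        seed=seed,
        leading_edge_size=leading_edge,
    )


def top_tail_size(n_genes: int, fraction: float = 0.02) -> int:
    """Number of genes in the constrained tail: floor(n_genes × fraction)."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if n_genes < 0:
        raise ValueError("n_genes must be non-negative")
    return math.floor(n_genes * fraction)


def hypergeometric_overrep(
    ranked: RankedGenome, gene_set: GeneSet, fraction: float = 0.02
) -> OverrepResult:
    """Upper-tail hypergeometric over-representation in the top tail.

    P(X >= k) where the universe is the ranked genome (N genes, K set
    members) and the draw is the top floor(N × fraction) most
    constrained genes, k of which are set members.
    """
    mask = _hit_mask(ranked, gene_set)
    n_universe = mask.size
    k_in_universe = int(mask.sum())
    tail_n = top_tail_size(n_universe, fraction)
    if tail_n == 0:
        raise ValueError(
            f"degenerate tail: floor({n_universe} x {fraction}) = 0 genes"
        )
    overlap_k = int(mask[:tail_n].sum())
    p = float(sps.hypergeom.sf(overlap_k - 1, n_universe, k_in_universe, tail_n))
    return OverrepResult(
        set_name=gene_set.name,
        universe_n=n_universe,
        tail_n=tail_n,
        set_k_in_universe=k_in_universe,
        overlap_k=overlap_k,
        p_value=min(p, 1.0),
    )


def enrichment_table(results) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
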