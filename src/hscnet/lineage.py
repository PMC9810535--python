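"""Permutation z-scores for gene-set enrichment across cell lineages.

Given log2-normalized expression profiles (genes x cell types) and a gene
set, the observed statistic per cell type is the mean expression of the
set; random gene sets of the same size drawn from the profiled genes give
a permutation null, and the enrichment is

    z = (y_obs - mean(y_perm)) / sd(y_perm)

computed per cell type with the same permutation draws scored on every
column. When the number of possible subsets is small the null is
enumerated exhaustively instead of sampled.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

__all__ = ["LineageEnrichment", "lineage_zscore"]

EXHAUSTIVE_LIMIT = 10_000


@dataclass
class LineageEnrichment:
    cell_type: str
    y_obs: float
    perm_mean: float
    perm_sd: float
    z: float
    degenerate: bool = False


def lineage_zscore(
    profiles: pd.DataFrame,
    gene_set,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    exhaustive: bool | None = None,
    match_expression_decile: bool = False,
) -> list[LineageEnrichment]:
    """Enrichment z-score of ``gene_set`` in each cell-type column.

    ``profiles`` has genes as rows and cell types as columns. Permuted sets
    are drawn uniformly without replacement from all profiled genes (or,
    with ``match_expression_decile``, from the same overall-mean deciles as
    the tested genes, as a sensitivity analysis). ``exhaustive=None``
    auto-enables full subset enumeration when there are at most
    ``EXHAUSTIVE_LIMIT`` subsets. A zero permutation s.d. yields z = 0 with
    the ``degenerate`` flag set.
    """
    genes = profiles.index
    gene_set = list(dict.fromkeys(gene_set))
    missing = [g for g in gene_set if g not in genes]
    if missing:
        raise KeyError(f"gene set members absent from profiles: {missing}")
    k = len(gene_set)
    if k == 0 or k >= len(genes):
        raise ValueError("gene set must be non-empty and a strict subset of profiled genes")

    mat = profiles.to_numpy(dtype=float)
    y_obs = profiles.loc[gene_set].to_numpy(dtype=float).mean(axis=0)

    if exhaustive is None:
        exhaustive = comb(len(genes), k) <= EXHAUSTIVE_LIMIT

    if match_expression_decile and not exhaustive:
        overall = mat.mean(axis=1)
        deciles = pd.qcut(overall, 10, labels=False, duplicates="drop")
        pools = {d: np.flatnonzero(deciles == d) for d in np.unique(deciles)}
        set_idx = [genes.get_loc(g) for g in gene_set]
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        perm_means = np.empty((n_perm, mat.shape[1]))
        for i in range(n_perm):
            draw = [int(rng.choice(pools[deciles[j]])) for j in set_idx]
            perm_means[i] = mat[draw].mean(axis=0)
    elif exhaustive:
        idx_all = np.arange(len(genes))
        perm_means = np.array(
            [mat[list(c)].mean(axis=0) for c in combinations(idx_all, k)]
        )
    else:
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        perm_means = np.empty((n_perm, mat.shape[1]))
        for i in range(n_perm):
            draw = rng.choice(len(genes), size=k, replace=False)
            perm_means[i] = mat[draw].mean(axis=0)

    mu = perm_means.mean(axis=0)
    sd = perm_means.std(axis=0)

    out = []
    for j, ct in enumerate(profiles.columns):
        if sd[j] > 0:
            out.append(LineageEnrichment(str(ct), float(y_obs[j]), float(mu[j]),
                                         float(sd[j]), float((y_obs[j] - mu[j]) / sd[j])))
        else:
            out.append(LineageEnrichment(str(ct), float(y_obs[j]), float(mu[j]),
                                         0.0, 0.0, degenerate=True))
    return out
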