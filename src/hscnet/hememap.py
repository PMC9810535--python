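"""cisRE catalog construction and accessibility-expression link scoring.

A catalog of candidate cis-regulatory elements (cisREs) is built by
merging accessible-chromatin peaks across hematopoietic populations. Each
cisRE is then linked to genes whose TSS lies within a distance window by
correlating accessibility with expression across the shared population
axis; significance comes from an empirical trans-pair null (random
cisRE-gene pairs on different chromosomes) with Benjamini-Hochberg FDR
control. Links are weighted by accessibility in the stem-cell population
to select a stem-cell-specific regulatory network.

The scoring internals (window, trans null, min-max accessibility
weighting) are a principled reconstruction from the stated ingredients;
every constant is exposed as an argument.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomicInterval, merge

logger = logging.getLogger(__name__)

__all__ = [
    "HSCNetwork",
    "build_cisre_catalog",
    "score_links",
    "select_hsc_network",
    "motif_similarity",
]


def build_cisre_catalog(
    peak_sets: dict[str, Sequence[GenomicInterval]],
) -> tuple[list[GenomicInterval], pd.DataFrame]:
    """Merge per-population peak sets into a cisRE catalog.

    Returns the merged catalog and a boolean cisRE x population matrix
    flagging which populations' peaks overlap each catalog element.
    """
    if not peak_sets:
        raise ValueError("need at least one population peak set")
    catalog = merge(iv for peaks in peak_sets.values() for iv in peaks)
    flags = pd.DataFrame(
        False,
        index=[f"{iv.chrom}:{iv.start}-{iv.end}" for iv in catalog],
        columns=list(peak_sets),
    )
    # catalog elements are disjoint and sorted; flag by sweep per population
    by_chrom: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for i, iv in enumerate(catalog):
        by_chrom.setdefault(iv.chrom, []).append((i, iv))
    for pop, peaks in peak_sets.items():
        col = np.zeros(len(catalog), dtype=bool)
        for peak in peaks:
            for i, iv in by_chrom.get(peak.chrom, []):
                if iv.start < peak.end and peak.start < iv.end:
                    col[i] = True
        flags[pop] = col
    return catalog, flags


def _standardize_rows(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise z-scores and a validity mask (rows with nonzero variance)."""
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    ok = sd.ravel() > 0
    z = np.where(sd > 0, (mat - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return z, ok


def score_links(
    accessibility: pd.DataFrame,
    cisre_intervals: Sequence[GenomicInterval],
    expression: pd.DataFrame,
    tss: pd.DataFrame,
    window_bp: int = 500_000,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Score candidate cisRE-gene links across populations.

    ``accessibility`` is cisREs x populations (rows aligned with
    ``cisre_intervals``), ``expression`` genes x populations over the same
    ordered population axis, ``tss`` a gene-indexed table with ``chrom`` and
    ``pos``. Candidate pairs have the gene TSS within ``window_bp`` of the
    cisRE midpoint; r is the Pearson correlation across populations, the
    empirical one-sided P comes from random trans (different-chromosome)
    pairs, and q is the Benjamini-Hochberg adjustment.
    """
    if list(accessibility.columns) != list(expression.columns):
        raise ValueError("accessibility and expression must share the ordered population axis")
    if len(cisre_intervals) != accessibility.shape[0]:
        raise ValueError("cisre_intervals must align with accessibility rows")

    acc_z, acc_ok = _standardize_rows(accessibility.to_numpy(dtype=float))
    exp_z, exp_ok = _standardize_rows(expression.to_numpy(dtype=float))
    n_pop = accessibility.shape[1]
    genes = expression.index

    tss = tss.loc[tss.index.intersection(genes)]
    gene_pos = {g: (row["chrom"], int(row["pos"])) for g, row in tss.iterrows()}
    gene_loc = {g: i for i, g in enumerate(genes)}
    chrom_of = np.array([iv.chrom for iv in cisre_intervals])
    mids = np.array([iv.midpoint for iv in cisre_intervals])

    rows = []
    n_skipped = 0
    for g, (chrom, pos) in gene_pos.items():
        gi = gene_loc[g]
        cand = np.flatnonzero((chrom_of == chrom) & (np.abs(mids - pos) <= window_bp))
        for ci in cand:
            if not (acc_ok[ci] and exp_ok[gi]):
                n_skipped += 1
                continue
            r = float(acc_z[ci] @ exp_z[gi] / n_pop)
            rows.append((accessibility.index[ci], ci, g, int(mids[ci] - pos), r))
    if n_skipped:
        logger.info("score_links: skipped %d constant-vector pairs", n_skipped)

    links = pd.DataFrame(rows, columns=["cisre", "cisre_idx", "gene", "distance_bp", "r"])
    if links.empty:
        links["p_emp"] = links["q"] = links["r"]
        return links

    # trans null: random cisRE x gene pairs on different chromosomes
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    gene_chrom = np.array([gene_pos.get(g, (None, 0))[0] for g in genes], dtype=object)
    valid_c = np.flatnonzero(acc_ok)
    valid_g = np.flatnonzero(exp_ok & (gene_chrom != None))  # noqa: E711
    if len(valid_c) == 0 or len(valid_g) == 0 or (
        len(set(chrom_of[valid_c])) == 1
        and set(chrom_of[valid_c]) == set(gene_chrom[valid_g])
    ):
        raise ValueError(
            "cannot form trans null pairs: need cisREs and genes on "
            "different chromosomes"
        )
    null_r = np.empty(n_perm)
    filled = 0
    while filled < n_perm:
        ci = valid_c[rng.integers(len(valid_c), size=n_perm)]
        gi = valid_g[rng.integers(len(valid_g), size=n_perm)]
        trans = chrom_of[ci] != gene_chrom[gi]
        take = min(int(trans.sum()), n_perm - filled)
        sel = np.flatnonzero(trans)[:take]
        null_r[filled:filled + take] = np.einsum(
            "ij,ij->i", acc_z[ci[sel]], exp_z[gi[sel]]
        ) / n_pop
        filled += take

    null_sorted = np.sort(null_r)
    n_ge = n_perm - np.searchsorted(null_sorted, links["r"].to_numpy(), side="left")
    links["p_emp"] = (1 + n_ge) / (n_perm + 1)
    links["q"] = stats.false_discovery_control(links["p_emp"], method="bh")
    return links


@dataclass
class HSCNetwork:
    """Stem-cell regulatory network: retained links plus member genes."""

    links: pd.DataFrame
    genes: list[str]


def select_hsc_network(
    links: pd.DataFrame,
    hsc_accessibility: pd.Series,
    q_thresh: float = 0.05,
) -> HSCNetwork:
    """Select links significant and accessible in the stem-cell population.

    The HemeMap-style score is r times the min-max-normalized stem-cell
    accessibility of the cisRE; a link is retained iff q < ``q_thresh`` and
    the cisRE is open (accessibility > 0) in the stem-cell population.
    """
    acc = hsc_accessibility.reindex(links["cisre"]).to_numpy(dtype=float)
    rng_ = acc[np.isfinite(acc)]
    lo, hi = (rng_.min(), rng_.max()) if len(rng_) else (0.0, 0.0)
    norm = (acc - lo) / (hi - lo) if hi > lo else np.zeros_like(acc)
    out = links.copy()
    out["hsc_accessibility"] = acc
    out["hememap_score"] = out["r"] * norm
    keep = (out["q"] < q_thresh) & (out["hsc_accessibility"] > 0)
    out = out[keep].reset_index(drop=True)
    return HSCNetwork(out, sorted(out["gene"].unique()))


def _revcomp_pfm(mat: np.ndarray) -> np.ndarray:
    # rows ordered A, C, G, T: complement = row reversal; then reverse columns
    return mat[::-1, ::-1]


def _normalize_pfm(mat: np.ndarray) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != 4:
        raise ValueError("PFM must be 4 x w")
    sums = mat.sum(axis=0)
    if np.any(sums <= 0):
        raise ValueError("PFM has empty columns")
    return mat / sums


def _best_alignment(a: np.ndarray, b: np.ndarray, min_overlap: int):
    """Max Pearson r over offsets and orientations of b against a."""
    best = (-np.inf, 0, "+")
    for orient, bo in (("+", b), ("-", _revcomp_pfm(b))):
        wa, wb = a.shape[1], bo.shape[1]
        for off in range(-(wb - min_overlap), wa - min_overlap + 1):
            lo_a, hi_a = max(0, off), min(wa, off + wb)
            if hi_a - lo_a < min_overlap:
                continue
            sub_a = a[:, lo_a:hi_a].ravel()
            sub_b = bo[:, lo_a - off:hi_a - off].ravel()
            if sub_a.std() == 0 or sub_b.std() == 0:
                continue
            r = float(np.corrcoef(sub_a, sub_b)[0, 1])
            if r > best[0]:
                best = (r, off, orient)
    return best


def motif_similarity(
    a: np.ndarray,
    b: np.ndarray,
    min_overlap: int = 5,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, int, str, float]:
    """Best-alignment Pearson similarity of two position frequency matrices.

    Frequencies are column-normalized; r is computed over the flattened
    overlapping columns at every offset with at least ``min_overlap``
    columns, in both orientations (forward and reverse complement).
    Significance comes from column-shuffled copies of ``b``. Returns
    (best_r, offset, orientation, p_perm).
    """
    a = _normalize_pfm(a)
    b = _normalize_pfm(b)
    if a.shape[1] < min_overlap or b.shape[1] < min_overlap:
        raise ValueError(f"both motifs must have width >= {min_overlap}")
    best_r, offset, orient = _best_alignment(a, b, min_overlap)
    if not np.isfinite(best_r):
        raise ValueError("degenerate (uniform) motif: correlation undefined")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    exceed = 0
    for _ in range(n_perm):
        null_b = b[:, rng.permutation(b.shape[1])]
        r, _, _ = _best_alignment(a, null_b, min_overlap)
        if r >= best_r:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return best_r, offset, orient, p
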