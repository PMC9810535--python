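"""Transcription-factor footprint statistics within cisREs.

Covers aggregate transposase cleavage profiles around motifs, pairwise
footprint co-occurrence (two-sided hypergeometric), occupancy enrichment
of ChIP peaks in cisREs by genome permutation, edge-to-edge footprint
spacing, and paired cross-lineage signal contrasts. Footprint *calling*
(posterior estimation from cut counts) is upstream of this package;
posteriors arrive as inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import Genome, GenomicInterval, interval_arrays, merge, random_placement

logger = logging.getLogger(__name__)

__all__ = [
    "Footprint",
    "CleavageProfile",
    "OccupancyEnrichment",
    "cleavage_profile",
    "cooccurrence",
    "occupancy_enrichment",
    "footprint_spacing",
    "signal_contrast",
]


@dataclass(frozen=True)
class Footprint:
    interval: GenomicInterval
    tf: str
    posterior: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.posterior <= 1.0):
            raise ValueError("posterior must be in [0, 1]")


@dataclass
class CleavageProfile:
    """Aggregate per-base cleavage probability over motif +/- flank."""

    prob: np.ndarray
    n_sites: int
    motif_width: int
    flank: int


def cleavage_profile(
    cut_counts: dict[str, np.ndarray],
    sites: Sequence[Footprint | GenomicInterval],
    flank: int = 250,
) -> CleavageProfile:
    """Aggregate cleavage probability around motif instances.

    ``cut_counts`` maps chromosome to a per-base integer cut-count track.
    All sites must share one motif width; windows truncated by a chromosome
    edge are skipped with a logged count. Minus-strand windows are reversed
    before summation, and the summed counts are normalized to a probability
    profile (sums to 1).
    """
    ivs = [s.interval if isinstance(s, Footprint) else s for s in sites]
    if not ivs:
        raise ValueError("no sites provided")
    widths = {iv.width for iv in ivs}
    if len(widths) != 1:
        raise ValueError(f"sites must share one motif width, got {sorted(widths)}")
    w = widths.pop()
    total = np.zeros(w + 2 * flank, dtype=float)
    used = skipped = 0
    for iv in ivs:
        track = cut_counts.get(iv.chrom)
        lo, hi = iv.start - flank, iv.end + flank
        if track is None or lo < 0 or hi > len(track):
            skipped += 1
            continue
        window = np.asarray(track[lo:hi], dtype=float)
        if iv.strand == "-":
            window = window[::-1]
        total += window
        used += 1
    if skipped:
        logger.info("cleavage_profile: skipped %d truncated windows", skipped)
    if used == 0 or total.sum() <= 0:
        raise ValueError("no usable sites with nonzero cut counts")
    return CleavageProfile(total / total.sum(), used, w, flank)


def _cisre_index(
    cisres: Sequence[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-chromosome (positions-in-list, starts, ends) for fast overlap tests."""
    by_chrom: dict[str, list[int]] = {}
    for i, iv in enumerate(cisres):
        by_chrom.setdefault(iv.chrom, []).append(i)
    out = {}
    for chrom, idxs in by_chrom.items():
        idxs = np.asarray(idxs)
        out[chrom] = (
            idxs,
            np.array([cisres[i].start for i in idxs], dtype=np.int64),
            np.array([cisres[i].end for i in idxs], dtype=np.int64),
        )
    return out


def _overlap_mask_indexed(
    cis_index: dict, n: int, intervals: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean per-cisRE: overlaps >=1 of ``intervals`` (merged internally)."""
    merged = interval_arrays(merge(intervals))
    out = np.zeros(n, dtype=bool)
    for chrom, (idxs, cs, ce) in cis_index.items():
        arrs = merged.get(chrom)
        if arrs is None:
            continue
        starts, ends = arrs  # sorted, disjoint: ends are increasing
        pos = np.searchsorted(starts, ce, side="left")
        hit = (pos > 0) & (ends[np.maximum(pos - 1, 0)] > cs)
        out[idxs] = hit
    return out


def _overlap_mask(
    cisres: Sequence[GenomicInterval], intervals: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean per-cisRE: overlaps >=1 of ``intervals``."""
    return _overlap_mask_indexed(_cisre_index(cisres), len(cisres), intervals)


def _hypergeom_two_sided(N: int, K: int, n: int, k: int) -> float:
    """Two-sided hypergeometric P by summing point masses <= mass(k)."""
    lo = max(0, n - (N - K))
    hi = min(K, n)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, N, K, n)
    obs = stats.hypergeom.pmf(k, N, K, n)
    return float(min(1.0, pmf[pmf <= obs * (1 + 1e-7)].sum()))


def cooccurrence(
    footprints_by_tf: dict[str, Sequence[Footprint | GenomicInterval]],
    cisres: Sequence[GenomicInterval],
) -> pd.DataFrame:
    """Pairwise TF footprint co-occurrence in cisREs.

    A TF is a member of a cisRE when at least one of its footprints
    overlaps it. For a pair, the overlap count k of the two membership sets
    is tested against the hypergeometric null (drawing |B| cisREs from N of
    which |A| are A-members), two-sided by the method of small P values.
    """
    if len(footprints_by_tf) < 2:
        raise ValueError("need at least two TFs")
    if not cisres:
        raise ValueError("empty cisRE list")
    N = len(cisres)
    members = {}
    for tf, fps in footprints_by_tf.items():
        ivs = [f.interval if isinstance(f, Footprint) else f for f in fps]
        members[tf] = _overlap_mask(cisres, ivs) if ivs else np.zeros(N, bool)
        if not members[tf].any():
            logger.warning("cooccurrence: TF %s absent from all cisREs", tf)
    rows = []
    tfs = list(footprints_by_tf)
    for i, ta in enumerate(tfs):
        for tb in tfs[i + 1:]:
            K, n = int(members[ta].sum()), int(members[tb].sum())
            k = int((members[ta] & members[tb]).sum())
            p = 1.0 if (K == 0 or n == 0 or K == N or n == N) else _hypergeom_two_sided(N, K, n, k)
            rows.append((ta, tb, K, n, k, p))
    return pd.DataFrame(rows, columns=["tf_a", "tf_b", "n_a", "n_b", "k", "p"])


@dataclass
class OccupancyEnrichment:
    observed: int
    perm_mean: float
    perm_sd: float
    z: float
    p_emp: float
    degenerate: bool = False


def occupancy_enrichment(
    cisres: Sequence[GenomicInterval],
    peaks: Sequence[GenomicInterval],
    genome: Genome,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> OccupancyEnrichment:
    """Enrichment of ChIP peaks in cisREs versus genome-permuted peaks.

    The observed statistic is the number of cisREs overlapping at least one
    peak; the null re-places an equal number of length-matched peaks
    uniformly across the genome ``n_perm`` times. The empirical P is
    (1 + #perm >= obs) / (n_perm + 1).
    """
    if not peaks:
        raise ValueError("empty peak list")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cis_index = _cisre_index(cisres)
    n = len(cisres)
    obs = int(_overlap_mask_indexed(cis_index, n, peaks).sum())
    null = np.empty(n_perm)
    for i in range(n_perm):
        placed = random_placement(peaks, genome, rng)
        null[i] = _overlap_mask_indexed(cis_index, n, placed).sum()
    mu, sd = float(null.mean()), float(null.std())
    p = float((1 + (null >= obs).sum()) / (n_perm + 1))
    if sd == 0:
        return OccupancyEnrichment(obs, mu, 0.0, 0.0, p, degenerate=True)
    return OccupancyEnrichment(obs, mu, sd, (obs - mu) / sd, p)


def footprint_spacing(
    footprints_by_tf: dict[str, Sequence[Footprint | GenomicInterval]],
    cisres: Sequence[GenomicInterval],
    tf_a: str,
    tf_b: str,
) -> tuple[list[float], float]:
    """Nearest edge-to-edge distance between two TFs' footprints per cisRE.

    For each cisRE containing footprints of both TFs, the distance is the
    minimum over footprint pairs of max(0, gap); overlapping footprints are
    at distance 0. Returns the per-cisRE distances and their mean.
    """
    def _ivs(tf: str) -> list[GenomicInterval]:
        return [f.interval if isinstance(f, Footprint) else f
                for f in footprints_by_tf.get(tf, [])]

    ivs_a, ivs_b = _ivs(tf_a), _ivs(tf_b)
    dists: list[float] = []
    for cisre in cisres:
        in_a = [iv for iv in ivs_a if iv.chrom == cisre.chrom
                and iv.start < cisre.end and cisre.start < iv.end]
        in_b = [iv for iv in ivs_b if iv.chrom == cisre.chrom
                and iv.start < cisre.end and cisre.start < iv.end]
        if not in_a or not in_b:
            continue
        d = min(
            max(0, max(a.start, b.start) - min(a.end, b.end))
            for a in in_a for b in in_b
        )
        dists.append(float(d))
    if not dists:
        raise ValueError(f"no cisRE contains footprints of both {tf_a} and {tf_b}")
    return dists, float(np.mean(dists))


def signal_contrast(
    signal_by_celltype: pd.DataFrame,
    reference_celltype: str,
    posteriors: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired Wilcoxon signed-rank contrasts of footprint signal.

    ``signal_by_celltype`` holds one row per footprint and one column per
    cell type of normalized signal; each non-reference cell type is tested
    against the reference over the paired footprints (two-sided). Also
    returns the matrix sorted by footprint posterior descending (heatmap
    convention) when ``posteriors`` is given.
    """
    if reference_celltype not in signal_by_celltype.columns:
        raise KeyError(f"reference cell type {reference_celltype!r} not in matrix")
    ref = signal_by_celltype[reference_celltype].to_numpy(dtype=float)
    rows = []
    for ct in signal_by_celltype.columns:
        if ct == reference_celltype:
            continue
        diff = signal_by_celltype[ct].to_numpy(dtype=float) - ref
        if np.all(diff == 0):
            rows.append((ct, 0.0, 1.0))
            continue
        res = stats.wilcoxon(diff, alternative="two-sided")
        rows.append((ct, float(res.statistic), float(res.pvalue)))
    table = pd.DataFrame(rows, columns=["cell_type", "statistic", "p"])
    sorted_mat = signal_by_celltype
    if posteriors is not None:
        order = posteriors.reindex(signal_by_celltype.index).sort_values(ascending=False).index
        sorted_mat = signal_by_celltype.loc[order]
    return table, sorted_mat
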