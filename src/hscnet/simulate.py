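"""Synthetic-data generators with planted ground truth for every pipeline stage.

Each generator is a pure function of its configuration (including the
seed) and emits the planted truth alongside the data; the truth is meant
for evaluation only and is never consumed by the analysis stages.

What the generators emulate, in order: two-condition negative-binomial
scRNA-seq counts of a perturbation experiment with a small planted DE
fraction; bulk expression profiles across hematopoietic lineages with a
stemness-graded gene set; paired accessibility/expression matrices across
populations with planted peak-gene links; TF footprint landscapes with
planted co-occurrence; distance-decay contact maps with planted loops of
condition-dependent strength; and an expression + survival cohort where
planted network enrichment carries a specified hazard ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.special import expit

from .footprints import Footprint
from .genome import Genome, GenomicInterval
from .loops import ContactMap, Loop

__all__ = [
    "ScSimConfig",
    "CohortSimConfig",
    "MultiomeSim",
    "FootprintSim",
    "gen_sc_counts",
    "gen_lineage_profiles",
    "gen_multiome",
    "gen_footprint_landscape",
    "gen_contact_map",
    "gen_cohort",
    "default_genome",
]

DEFAULT_TFS = ("ETS", "RUNX", "JUN", "KLF", "CTCF", "GATA")


def default_genome() -> Genome:
    """Small two-chromosome genome used by the footprint simulations."""
    return Genome(("chr1", "chr2"), (2_000_000, 1_000_000))


# ---------------------------------------------------------------------------
# single-cell counts


@dataclass(frozen=True)
class ScSimConfig:
    """Two-condition scRNA-seq simulation settings.

    Counts are gamma-Poisson (negative binomial) with per-cell size
    factors; planted DE genes are shifted by ``de_log2fc`` in condition B
    (half up, half down); extra dropout is applied with probability
    decreasing in the gene's expected count (logistic in log mean with
    slope ``dropout_logit_slope``).
    """

    n_cells_per_condition: int = 2000
    n_genes: int = 2000
    de_fraction: float = 0.05
    de_log2fc: float = 1.0
    nb_dispersion: float = 0.4
    dropout_logit_slope: float = 1.0
    dropout_midpoint: float = 0.1
    min_mean: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ValueError("de_fraction must be in [0, 1]")
        if self.n_genes <= 0 or self.n_cells_per_condition <= 0:
            raise ValueError("dimensions must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


def gen_sc_counts(cfg: ScSimConfig) -> tuple[AnnData, pd.DataFrame]:
    """Simulate counts and return (AnnData, planted-truth table).

    Condition "A" is the control; planted genes carry a signed log2 effect
    in condition "B" (positive = up after perturbation). The truth table
    lists each planted gene with its signed effect.
    """
    rng = np.random.default_rng(cfg.seed)
    n_c, n_g = cfg.n_cells_per_condition, cfg.n_genes
    genes = np.array([f"g{i:05d}" for i in range(n_g)])

    # mean panel of genes surviving standard expression filtering
    base_mu = np.maximum(rng.lognormal(mean=0.0, sigma=1.0, size=n_g), cfg.min_mean)
    size_factors = rng.lognormal(mean=0.0, sigma=0.3, size=2 * n_c)

    n_de = int(round(cfg.de_fraction * n_g))
    de_idx = rng.choice(n_g, size=n_de, replace=False)
    effect = np.zeros(n_g)
    half = n_de // 2
    effect[de_idx[:half]] = cfg.de_log2fc        # up in perturbed condition
    effect[de_idx[half:]] = -cfg.de_log2fc       # down in perturbed condition

    cond = np.array(["A"] * n_c + ["B"] * n_c)
    mu = np.outer(size_factors, base_mu)
    mu[n_c:] *= 2.0 ** effect

    shape = 1.0 / cfg.nb_dispersion
    lam = rng.gamma(shape, scale=mu / shape)
    counts = rng.poisson(lam).astype(np.int64)

    # mean-dependent extra dropout (zero inflation strongest for low means)
    p_drop = expit(
        -cfg.dropout_logit_slope
        * np.log(np.maximum(mu, 1e-12) / cfg.dropout_midpoint)
    )
    counts[rng.random(counts.shape) < p_drop] = 0

    adata = AnnData(
        X=sp.csr_matrix(counts),
        obs=pd.DataFrame(
            {"condition": cond},
            index=[f"cell{i:05d}" for i in range(2 * n_c)],
        ),
        var=pd.DataFrame(index=genes),
    )
    truth = pd.DataFrame(
        {"gene": genes[de_idx], "effect": effect[de_idx]}
    ).set_index("gene")
    return adata, truth


# ---------------------------------------------------------------------------
# lineage profiles


def gen_lineage_profiles(
    n_cell_types: int = 20,
    gradient_set_size: int = 100,
    n_genes: int = 2000,
    gradient: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Log2-normalized lineage expression profiles with a planted
    stemness-graded gene set.

    The first column ("HSC") is the stem-cell population; planted genes
    decline linearly by ``gradient`` log2 units from HSC to the most
    differentiated column, on top of gene-specific baselines and noise.
    """
    if n_cell_types < 2:
        raise ValueError("need at least 2 cell types")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    cols = ["HSC"] + [f"CT{j:02d}" for j in range(1, n_cell_types)]
    baseline = rng.normal(5.0, 1.0, size=n_genes)
    mat = baseline[:, None] + rng.normal(0.0, 0.5, size=(n_genes, n_cell_types))
    planted = list(rng.choice(n_genes, size=gradient_set_size, replace=False))
    ramp = gradient * (1.0 - np.arange(n_cell_types) / (n_cell_types - 1))
    mat[planted] += ramp[None, :]
    profiles = pd.DataFrame(mat, index=genes, columns=cols)
    return profiles, [genes[i] for i in planted]


# ---------------------------------------------------------------------------
# multiome (accessibility + expression across populations)


@dataclass
class MultiomeSim:
    accessibility: pd.DataFrame
    cisre_intervals: list[GenomicInterval]
    expression: pd.DataFrame
    tss: pd.DataFrame
    truth_links: pd.DataFrame


def gen_multiome(
    n_populations: int = 18,
    n_genes: int = 200,
    n_peaks: int = 600,
    linked_fraction: float = 0.3,
    link_r: float = 0.8,
    window_bp: int = 500_000,
    seed: int = 0,
) -> MultiomeSim:
    """Cross-population accessibility/expression with planted peak-gene links.

    Linked (peak, gene) pairs share a latent population factor so that
    their cross-population Pearson correlation is ~``link_r``; unlinked
    peaks and genes are independent. Genes alternate between two
    chromosomes so that trans (different-chromosome) null pairs exist.
    """
    if n_populations < 5:
        raise ValueError("need at least 5 populations")
    rng = np.random.default_rng(seed)
    pops = ["HSC"] + [f"P{j:02d}" for j in range(1, n_populations)]
    genes = [f"g{i:04d}" for i in range(n_genes)]
    chroms = ["chr1" if i % 2 == 0 else "chr2" for i in range(n_genes)]
    tss_pos = [1_000_000 + (i // 2) * 2_000_000 for i in range(n_genes)]
    tss = pd.DataFrame(
        {"chrom": chroms, "pos": tss_pos, "strand": "+"}, index=pd.Index(genes, name="gene")
    )

    expr = rng.normal(0.0, 1.0, size=(n_genes, n_populations))
    acc = rng.normal(0.0, 1.0, size=(n_peaks, n_populations))

    n_linked = int(round(linked_fraction * n_peaks))
    linked_peaks = rng.choice(n_peaks, size=n_linked, replace=False)
    linked_genes = rng.integers(0, n_genes, size=n_linked)
    a = np.sqrt(max(link_r, 0.0))
    b = np.sqrt(1.0 - max(link_r, 0.0))
    rows = []
    intervals: list[GenomicInterval | None] = [None] * n_peaks
    factors: dict[int, np.ndarray] = {}  # one latent factor per linked gene
    for pk, gi in zip(linked_peaks, linked_genes):
        gi = int(gi)
        if gi not in factors:
            factors[gi] = rng.normal(0.0, 1.0, size=n_populations)
            expr[gi] = a * factors[gi] + b * rng.normal(0.0, 1.0, size=n_populations)
        f = factors[gi]
        acc[pk] = a * f + b * rng.normal(0.0, 1.0, size=n_populations)
        offset = int(rng.integers(-window_bp // 2, window_bp // 2))
        start = max(0, tss_pos[gi] + offset)
        intervals[pk] = GenomicInterval(chroms[gi], start, start + 500)
        rows.append((pk, genes[gi]))
    # unlinked peaks: placed near random genes (still candidate pairs)
    for pk in range(n_peaks):
        if intervals[pk] is None:
            gi = int(rng.integers(0, n_genes))
            offset = int(rng.integers(-window_bp // 2, window_bp // 2))
            start = max(0, tss_pos[gi] + offset)
            intervals[pk] = GenomicInterval(chroms[gi], start, start + 500)

    peak_ids = [f"peak{i:04d}" for i in range(n_peaks)]
    accessibility = pd.DataFrame(2.0 + acc, index=peak_ids, columns=pops)
    expression = pd.DataFrame(5.0 + expr, index=genes, columns=pops)
    truth = pd.DataFrame(
        [(peak_ids[pk], g) for pk, g in rows], columns=["cisre", "gene"]
    )
    return MultiomeSim(accessibility, intervals, expression, tss, truth)


# ---------------------------------------------------------------------------
# footprint landscape


@dataclass
class FootprintSim:
    cisres: list[GenomicInterval]
    footprints_by_tf: dict[str, list[Footprint]]
    cut_counts: dict[str, np.ndarray]
    genome: Genome
    truth_pairs: dict[tuple[str, str], float] = field(default_factory=dict)


def _joint_bernoulli_p11(p_a: float, p_b: float, odds_ratio: float) -> float:
    """P(A and B) for given marginals and odds ratio (Plackett solution)."""
    if odds_ratio == 1.0:
        return p_a * p_b
    s = 1.0 + (p_a + p_b) * (odds_ratio - 1.0)
    disc = s * s - 4.0 * odds_ratio * (odds_ratio - 1.0) * p_a * p_b
    return (s - np.sqrt(disc)) / (2.0 * (odds_ratio - 1.0))


def gen_footprint_landscape(
    genome: Genome | None = None,
    n_cisres: int = 500,
    tf_names: Sequence[str] = DEFAULT_TFS,
    cooccur_pairs: dict[tuple[str, str], float] | None = None,
    base_prob: float = 0.3,
    motif_width: int = 15,
    cisre_width: int = 400,
    flank_rate: float = 5.0,
    protection: float = 0.2,
    seed: int = 0,
) -> FootprintSim:
    """Footprint landscape with planted TF co-occurrence.

    Each TF occupies a cisRE with marginal probability ``base_prob``;
    planted pairs co-occur at the given odds ratio (Plackett joint
    Bernoulli). Per-base cut-count tracks show Poisson cleavage at
    ``flank_rate`` outside motifs, reduced by ``protection`` within
    occupied motifs.
    """
    genome = genome or default_genome()
    cooccur_pairs = cooccur_pairs or {}
    for (a, b), orr in cooccur_pairs.items():
        if orr <= 0:
            raise ValueError("odds ratios must be positive")
        if a not in tf_names or b not in tf_names:
            raise ValueError(f"planted pair ({a}, {b}) not in tf_names")
    paired = [tf for pair in cooccur_pairs for tf in pair]
    if len(paired) != len(set(paired)):
        raise ValueError("each TF may appear in at most one planted pair")

    rng = np.random.default_rng(seed)
    template = [GenomicInterval("chr1", 0, cisre_width)] * n_cisres
    from .genome import random_placement  # local import avoids cycle at module load

    cisres = random_placement(template, genome, rng)

    # occupancy matrix cisRE x TF
    occ = {tf: rng.random(n_cisres) < base_prob for tf in tf_names}
    for (a, b), orr in cooccur_pairs.items():
        p11 = _joint_bernoulli_p11(base_prob, base_prob, orr)
        u = rng.random(n_cisres)
        both = u < p11
        only_a = (u >= p11) & (u < base_prob)
        only_b = (u >= base_prob) & (u < 2 * base_prob - p11)
        occ[a] = both | only_a
        occ[b] = both | only_b

    cut_counts = {
        c: rng.poisson(flank_rate, size=l).astype(np.int64)
        for c, l in zip(genome.chrom_names, genome.chrom_lengths)
    }
    footprints: dict[str, list[Footprint]] = {tf: [] for tf in tf_names}
    for i, cisre in enumerate(cisres):
        for t, tf in enumerate(tf_names):
            if not occ[tf][i]:
                continue
            max_off = cisre_width - motif_width
            start = cisre.start + int(rng.integers(0, max_off + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            iv = GenomicInterval(cisre.chrom, start, start + motif_width, strand)
            posterior = float(rng.beta(5, 2))
            footprints[tf].append(Footprint(iv, tf, posterior))
            track = cut_counts[iv.chrom]
            track[iv.start:iv.end] = rng.poisson(
                flank_rate * protection, size=motif_width
            )
    return FootprintSim(cisres, footprints, cut_counts, genome, dict(cooccur_pairs))


# ---------------------------------------------------------------------------
# contact maps


def gen_contact_map(
    loops: Sequence[tuple[int, int, float, float]],
    chrom_length: int = 20_000_000,
    resolution: int = 25_000,
    decay_exponent: float = 1.0,
    base_count: float = 100.0,
    anchor_width: int = 10_000,
    min_separation_bins: int = 21,
    seed: int = 0,
    chrom: str = "chr1",
) -> tuple[ContactMap, ContactMap, list[Loop]]:
    """Poisson contact maps for two conditions with planted loops.

    ``loops`` holds (anchor1_pos, anchor2_pos, strength_a, strength_b)
    tuples in bp. The expected count at bin distance d is
    base_count * max(d, 1)^(-decay_exponent); at a loop pixel it is
    multiplied by (1 + strength) for the respective condition. Anchors
    closer to the diagonal than ``min_separation_bins`` raise an error.
    """
    rng = np.random.default_rng(seed)
    n = chrom_length // resolution
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    expected = base_count * np.maximum(d, 1).astype(float) ** (-decay_exponent)

    loop_objs = []
    factors_a = np.ones((n, n))
    factors_b = np.ones((n, n))
    for p1, p2, sa, sb in loops:
        if p1 > p2:
            p1, p2 = p2, p1
        i, j = p1 // resolution, p2 // resolution
        if j - i < min_separation_bins:
            raise ValueError(
                f"loop anchors at bins ({i}, {j}) are closer than "
                f"{min_separation_bins} bins to the diagonal"
            )
        factors_a[i, j] = factors_a[j, i] = 1.0 + sa
        factors_b[i, j] = factors_b[j, i] = 1.0 + sb
        half = anchor_width // 2
        loop_objs.append(
            Loop(
                GenomicInterval(chrom, max(0, p1 - half), p1 + half),
                GenomicInterval(chrom, max(0, p2 - half), p2 + half),
            )
        )

    def draw(factors: np.ndarray) -> np.ndarray:
        iu = np.triu_indices(n)
        counts = np.zeros((n, n))
        counts[iu] = rng.poisson(expected[iu] * factors[iu])
        return counts + np.triu(counts, 1).T

    map_a = ContactMap(chrom, resolution, draw(factors_a))
    map_b = ContactMap(chrom, resolution, draw(factors_b))
    return map_a, map_b, loop_objs


# ---------------------------------------------------------------------------
# survival cohort


@dataclass(frozen=True)
class CohortSimConfig:
    """Expression + survival cohort simulation settings.

    Enriched patients carry the network genes up-shifted by
    ``network_shift`` log2 units; survival times are exponential with the
    hazard multiplied by ``true_hr`` for enriched patients; censoring is
    independent exponential calibrated to ``censor_rate``.
    """

    n_patients: int = 400
    enriched_fraction: float = 0.4
    true_hr: float = 2.0
    censor_rate: float = 0.3
    baseline_hazard: float = 1e-3
    network_shift: float = 1.0
    n_genes: int = 1000
    n_studies: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_hr <= 0:
            raise ValueError("true_hr must be positive")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ValueError("censor_rate must be in [0, 1)")


def gen_cohort(
    cfg: CohortSimConfig, network: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Simulate a cohort; returns (expression, clinical, enriched-truth).

    Expression is samples x genes on log2 scale with unit gene noise.
    Clinical columns: time (days), event, age, sex (0/1), study.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"g{i:04d}" for i in range(cfg.n_genes)]
    if network is None:
        network = genes[:50]
    network = [g for g in network if g in genes]
    samples = [f"s{i:04d}" for i in range(cfg.n_patients)]

    enriched = rng.random(cfg.n_patients) < cfg.enriched_fraction
    gene_means = rng.normal(5.0, 1.0, size=cfg.n_genes)
    X = gene_means[None, :] + rng.normal(0.0, 1.0, size=(cfg.n_patients, cfg.n_genes))
    net_idx = [genes.index(g) for g in network]
    X[np.ix_(enriched, net_idx)] += cfg.network_shift
    expr = pd.DataFrame(X, index=samples, columns=genes)

    hazard = cfg.baseline_hazard * np.where(enriched, cfg.true_hr, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    if cfg.censor_rate > 0:
        h_c = hazard * cfg.censor_rate / (1.0 - cfg.censor_rate)
        t_cens = rng.exponential(1.0 / h_c)
    else:
        t_cens = np.full(cfg.n_patients, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    clinical = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "age": rng.integers(18, 80, size=cfg.n_patients),
            "sex": rng.integers(0, 2, size=cfg.n_patients),
            "study": [f"S{i % cfg.n_studies}" for i in range(cfg.n_patients)],
        },
        index=samples,
    )
    truth = pd.Series(enriched, index=samples, name="enriched")
    return expr, clinical, truth
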