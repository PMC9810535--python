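"""Contact-map balancing and aggregate peak analysis of chromatin loops.

Contact maps are per-chromosome symmetric count matrices at fixed
resolution (25 kb default, matching the looping analyses this package
supports). Knight-Ruiz balancing equalizes row sums; aggregate peak
analysis (APA) averages balanced submatrices centered on loop anchors and
summarizes focal enrichment as the peak-to-lower-left ratio (P2LL). Loops
are classified by CTCF-footprint anchors and by overlap with the cisREs
of network genes, and corner distributions of two cell states are
contrasted with a two-sided t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genome import GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "ContactMap",
    "Loop",
    "APAResult",
    "LoopClasses",
    "kr_balance",
    "apa",
    "classify_loops",
    "corner_contrast",
]


@dataclass
class ContactMap:
    """Symmetric binned contact matrix for one chromosome."""

    chrom: str
    resolution: int
    matrix: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(m, m.T):
            raise ValueError("contact matrix must be symmetric")
        if np.any(m < 0):
            raise ValueError("contact matrix must be nonnegative")
        self.matrix = m

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def bin_of(self, pos: int) -> int:
        return pos // self.resolution

    def balanced(self) -> np.ndarray:
        """Balanced matrix diag(w) M diag(w); masked bins become NaN."""
        if self.weights is None:
            raise ValueError("map has no balancing weights; run kr_balance first")
        w = self.weights
        return np.outer(w, w) * self.matrix


@dataclass(frozen=True)
class Loop:
    """A chromatin loop between two same-chromosome anchors, anchor1 upstream."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError("loop anchors must share a chromosome")
        if self.anchor1.start >= self.anchor2.start:
            raise ValueError("anchor1 must be upstream of anchor2")


def _kr_vector(A: np.ndarray, tol: float, max_iter: int) -> tuple[np.ndarray, bool]:
    """Knight-Ruiz inner-outer iteration on a positive-support matrix.

    Returns weights x with diag(x) A diag(x) having unit row sums, and a
    convergence flag. Adapted from the published bnewt scheme.
    """
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, Delta = 0.1, 3.0
    g, etamax = 0.9, 0.1
    eta = etamax
    rt = tol**2
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rho_km2 = rho_km1
    rout = rold = rho_km1
    mvp = 0
    while rout > rt and mvp < max_iter:
        k = 0
        y = e.copy()
        innertol = max(eta**2 * rout, rt)
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            alpha = rho_km1 / (p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                ind = ap < 0
                gamma = ((delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                ind = ynew > Delta
                gamma = ((Delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
            if k > n:
                break
        x = x * y
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rho_km2 = rho_km1
        rout = rho_km1
        mvp += k + 1
        rat = rout / rold
        rold = rout
        eta_o = eta
        eta = g * rat
        if g * eta_o**2 > 0.1:
            eta = max(eta, g * eta_o**2)
        eta = max(min(eta, etamax), 0.5 * tol / max(np.sqrt(rout), 1e-300))
    return x, rout <= rt


def _sinkhorn(A: np.ndarray, tol: float, max_iter: int = 20000) -> tuple[np.ndarray, bool]:
    """Iterated proportional scaling fallback for a symmetric matrix."""
    x = np.ones(A.shape[0])
    for _ in range(max_iter):
        s = x * (A @ x)
        if np.abs(s - 1.0).max() < tol:
            return x, True
        x = x / np.sqrt(s)
    s = x * (A @ x)
    return x, bool(np.abs(s - 1.0).max() < tol)


def kr_balance(
    cmap: ContactMap,
    tol: float = 1e-6,
    max_iter: int = 3000,
    min_nnz: int = 10,
) -> ContactMap:
    """Knight-Ruiz balance a contact map.

    Rows with fewer than ``min_nnz`` nonzero entries are masked (weight
    NaN) and excluded from balancing. The returned map's balanced matrix
    has all unmasked row sums equal to 1 within ``tol``. Falls back to
    iterated proportional scaling (logged) if the KR iteration stalls;
    raises on non-convergence or a fully-zero matrix.
    """
    M = cmap.matrix
    nnz = (M > 0).sum(axis=1)
    keep = nnz >= min_nnz
    if not keep.any():
        raise ValueError("contact matrix has no rows passing the min_nnz mask")
    A = M[np.ix_(keep, keep)]
    # masking can zero rows of the submatrix; drop those too
    inner = A.sum(axis=1) > 0
    if not inner.all():
        full = np.flatnonzero(keep)[~inner]
        keep = keep.copy()
        keep[full] = False
        A = M[np.ix_(keep, keep)]
    x, ok = _kr_vector(A, tol, max_iter)
    if not ok or not np.all(np.isfinite(x)) or np.any(x <= 0):
        logger.warning("kr_balance: KR iteration stalled; falling back to proportional scaling")
        x, ok = _sinkhorn(A, tol)
    if not ok:
        res = np.abs(x * (A @ x) - 1.0).max() if np.all(np.isfinite(x)) else np.inf
        raise RuntimeError(f"balancing failed to converge (max residual {res:.3g})")
    weights = np.full(cmap.n_bins, np.nan)
    weights[keep] = x
    return ContactMap(cmap.chrom, cmap.resolution, cmap.matrix, weights)


@dataclass
class APAResult:
    """Aggregate peak analysis summary over a loop set."""

    agg: np.ndarray
    p2ll: float
    n_loops_used: int
    corner_values: np.ndarray
    window_bins: int = 10
    corner: int = 6


def apa(
    cmap: ContactMap,
    loops: list[Loop],
    window_bins: int = 10,
    corner: int = 6,
) -> APAResult:
    """Aggregate peak analysis of ``loops`` on a balanced contact map.

    Averages the (2w+1) x (2w+1) balanced submatrix centered on each
    loop's anchor-bin pair, with anchor1 offsets as rows (downstream
    increasing downward) and anchor2 offsets as columns. Loops whose
    neighborhood crosses the matrix edge or the diagonal are excluded with
    a logged count. P2LL divides the center pixel by the mean of the
    corner x corner lower-left box (high rows, low columns: the decay-side
    background).
    """
    W = cmap.balanced()
    n = cmap.n_bins
    w = window_bins
    subs = []
    skipped = 0
    for loop in loops:
        i = cmap.bin_of(loop.anchor1.midpoint)
        j = cmap.bin_of(loop.anchor2.midpoint)
        if i > j:
            i, j = j, i
        if i - w < 0 or j + w >= n or (j - i) <= 2 * w:
            skipped += 1
            continue
        subs.append(W[i - w:i + w + 1, j - w:j + w + 1])
    if skipped:
        logger.info("apa: excluded %d loops near edge or diagonal", skipped)
    if not subs:
        raise ValueError("no usable loops for APA")
    # per-pixel sort canonicalizes summation order: the aggregate is
    # bit-identical under any permutation of the loop list
    stack = np.sort(np.stack(subs), axis=0)
    with np.errstate(invalid="ignore"):
        agg = np.nanmean(stack, axis=0)
    size = 2 * w + 1
    corner_vals = agg[size - corner:size, 0:corner].ravel()
    corner_mean = np.nanmean(corner_vals)
    center = agg[w, w]
    p2ll = float(center / corner_mean) if corner_mean > 0 else float("nan")
    return APAResult(agg, p2ll, len(subs), corner_vals, w, corner)


@dataclass
class LoopClasses:
    """Loop partition: all loops, network loops by CTCF-anchor status,
    and the genes contained within each loop's domain."""

    all: list[Loop]
    network: list[Loop]
    ctcf_network: list[Loop]
    nonctcf_network: list[Loop]
    loop_genes: dict[int, list[str]] = field(default_factory=dict)


def _anchor_overlaps_any(anchor: GenomicInterval, ivs) -> bool:
    return any(
        iv.chrom == anchor.chrom and iv.start < anchor.end and anchor.start < iv.end
        for iv in ivs
    )


def classify_loops(
    loops: list[Loop],
    ctcf_footprints,
    cisre_links,
    network_genes,
    gene_spans: dict[str, GenomicInterval] | None = None,
) -> LoopClasses:
    """Partition loops by network membership and CTCF anchors.

    ``cisre_links`` is an iterable of (cisre interval, gene) pairs; a loop
    belongs to the network when at least one anchor overlaps a cisRE linked
    to a gene in ``network_genes``. A network loop is CTCF-mediated when at
    least one anchor overlaps a CTCF footprint; otherwise non-CTCF. When
    ``gene_spans`` is given, genes whose span lies within the domain
    between anchors are assigned to each loop.
    """
    network_genes = set(network_genes)
    net_cisres = [iv for iv, g in cisre_links if g in network_genes]
    ctcf_ivs = [
        f.interval if hasattr(f, "interval") else f for f in ctcf_footprints
    ]
    network, ctcf_net, nonctcf_net = [], [], []
    loop_genes: dict[int, list[str]] = {}
    for idx, loop in enumerate(loops):
        in_net = (
            _anchor_overlaps_any(loop.anchor1, net_cisres)
            or _anchor_overlaps_any(loop.anchor2, net_cisres)
        )
        if in_net:
            network.append(loop)
            has_ctcf = (
                _anchor_overlaps_any(loop.anchor1, ctcf_ivs)
                or _anchor_overlaps_any(loop.anchor2, ctcf_ivs)
            )
            (ctcf_net if has_ctcf else nonctcf_net).append(loop)
        if gene_spans is not None:
            domain = (loop.anchor1.chrom, loop.anchor1.start, loop.anchor2.end)
            loop_genes[idx] = [
                g for g, span in gene_spans.items()
                if span.chrom == domain[0]
                and span.start >= domain[1]
                and span.end <= domain[2]
            ]
    return LoopClasses(list(loops), network, ctcf_net, nonctcf_net, loop_genes)


def _standardized_corner(res: APAResult) -> np.ndarray:
    """Corner values standardized against the whole aggregate window.

    Standardizing within each APA's own aggregate (rather than within the
    corner box) keeps the two conditions comparable while preserving any
    shift of the corner relative to its window.
    """
    mu = np.nanmean(res.agg)
    sd = np.nanstd(res.agg)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("zero-variance aggregate matrix")
    vals = res.corner_values[np.isfinite(res.corner_values)]
    return (vals - mu) / sd


def corner_contrast(
    apa_a: APAResult, apa_b: APAResult
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Contrast the standardized lower-left corner distributions of two
    APA results (two-sided t-test).

    Each corner distribution is standard-normalized within its own
    aggregate window; a nonsignificant P says the loop-background signal
    does not differ between the two cell states, so any P2LL difference
    reflects the peak, not the background.
    """
    za = _standardized_corner(apa_a)
    zb = _standardized_corner(apa_b)
    if za.std() == 0 or zb.std() == 0:
        raise ValueError("zero-variance corner distribution")
    t, p = stats.ttest_ind(za, zb)
    return za, zb, float(t), float(p)
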