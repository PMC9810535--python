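"""Per-sample gene-set enrichment and survival stratification for AML cohorts.

Implements the classical weighted Kolmogorov-Smirnov preranked GSEA
running sum with a gene-label permutation null, a per-sample ranking
metric (expression minus the study-centered cohort mean), Youden-J
optimal thresholding, Kaplan-Meier / log-rank / trend testing, Cox
proportional-hazards modelling (through lifelines, Efron ties), marginal
hazard curves, and the expression-cutoff stratification used for
CRISPR-essentiality contrasts in cell-line panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "SurvivalFit",
    "CoxResult",
    "KMResult",
    "preranked_gsea",
    "gsea_es",
    "sample_rank_metric",
    "youden_threshold",
    "km_logrank",
    "cox_model",
    "marginal_hazard_curve",
    "ccle_stratify_essentiality",
]


@dataclass
class EnrichmentResult:
    es: float
    nes: float
    p_perm: float
    call: str
    n_hits: int


def _running_sum(metric: np.ndarray, hit: np.ndarray, weight: float) -> np.ndarray:
    """Weighted K-S running sum over a descending-sorted ranking."""
    n = metric.size
    k = int(hit.sum())
    w = np.abs(metric) ** weight if weight != 0 else np.ones(n)
    denom = w[hit].sum()
    if denom <= 0:
        # all hit weights zero (e.g. zero metrics): fall back to unweighted
        w = np.ones(n)
        denom = float(k)
    step = np.where(hit, w / denom, -1.0 / (n - k))
    return np.cumsum(step)


def gsea_es(metric_sorted: np.ndarray, hit: np.ndarray, weight: float = 1.0) -> float:
    """Enrichment score: signed extremum of the running sum."""
    rs = _running_sum(metric_sorted, hit, weight)
    return float(rs[np.argmax(np.abs(rs))])


def _null_es_batch(
    metric: np.ndarray, k: int, weight: float, n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """ES for ``n_perm`` random same-size gene sets, vectorized over sets."""
    n = metric.size
    w = np.abs(metric) ** weight if weight != 0 else np.ones(n)
    idx = np.argsort(rng.random((n_perm, n)), axis=1)[:, :k]
    hw = w[idx]
    denom = hw.sum(axis=1)
    bad = denom <= 0
    if bad.any():
        hw[bad] = 1.0
        denom[bad] = float(k)
    step = np.full((n_perm, n), -1.0 / (n - k))
    step[np.arange(n_perm)[:, None], idx] = hw / denom[:, None]
    rs = np.cumsum(step, axis=1)
    return rs[np.arange(n_perm), np.argmax(np.abs(rs), axis=1)]


def preranked_gsea(
    ranked: pd.Series,
    gene_set,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> EnrichmentResult:
    """Preranked GSEA of ``gene_set`` against a gene -> metric ranking.

    The ranking is sorted descending; hits increment the running sum in
    proportion to |metric|^weight and misses decrement uniformly. The
    enrichment score is the signed extremum; the null permutes gene-set
    labels (random same-size sets), NES divides the ES by the mean
    magnitude of same-sign null scores, and the one-sided permutation P is
    computed within sign. Calls: enriched (nes > 0, p < 0.05), depleted
    (nes < 0, p < 0.05), else neutral.
    """
    ranked = ranked.dropna().sort_values(ascending=False)
    genes = ranked.index.to_numpy()
    metric = ranked.to_numpy(dtype=float)
    hit = np.isin(genes, list(gene_set))
    k = int(hit.sum())
    n = genes.size
    if k < 3:
        raise ValueError("gene set shares fewer than 3 genes with the ranking")
    if k >= n:
        raise ValueError("gene set covers the whole ranking")
    es = gsea_es(metric, hit, weight)

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    null = _null_es_batch(metric, k, weight, n_perm, rng)

    if es > 0:
        same = null[null > 0]
    elif es < 0:
        same = null[null < 0]
    else:
        same = np.array([])
    if same.size:
        nes = es / np.abs(same).mean()
        p = (1 + int((np.abs(same) >= abs(es)).sum())) / (1 + same.size)
    else:
        nes = 0.0
        p = 1.0 if es == 0 else 1.0 / (n_perm + 1)
    if p < 0.05 and nes > 0:
        call = "enriched"
    elif p < 0.05 and nes < 0:
        call = "depleted"
    else:
        call = "neutral"
    return EnrichmentResult(float(es), float(nes), float(p), call, k)


def sample_rank_metric(
    expr: pd.DataFrame,
    sample_id,
    study: pd.Series | None = None,
) -> pd.Series:
    """Per-sample ranking metric: expression minus the cohort mean.

    ``expr`` is samples x genes on log2 scale. With ``study`` labels, each
    gene is mean-centered within study first, so merged cohorts rank on a
    within-study log fold change versus the cohort average.
    """
    if sample_id not in expr.index:
        raise KeyError(f"sample {sample_id!r} not in cohort")
    if study is not None:
        centered = expr - expr.groupby(np.asarray(study)).transform("mean")
    else:
        centered = expr - expr.mean(axis=0)
    metric = centered.loc[sample_id] - centered.mean(axis=0)
    n_missing = int(metric.isna().sum())
    if n_missing:
        logger.info("sample_rank_metric: dropped %d missing genes", n_missing)
        metric = metric.dropna()
    return metric


def youden_threshold(score, outcome) -> float:
    """Optimal dichotomizing cut maximizing Youden's J = sens + spec - 1.

    Candidates are the midpoints of sorted unique scores; a sample is
    called positive when score > threshold. Ties in J break toward the
    lower threshold.
    """
    score = np.asarray(score, dtype=float)
    outcome = np.asarray(outcome, dtype=bool)
    if outcome.all() or (~outcome).all():
        raise ValueError("both outcome classes must be present")
    uniq = np.unique(score)
    if uniq.size < 2:
        raise ValueError("score is constant")
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos = outcome.sum()
    n_neg = outcome.size - n_pos
    best_j, best_t = -np.inf, cands[0]
    for t in cands:
        pred = score > t
        sens = (pred & outcome).sum() / n_pos
        spec = (~pred & ~outcome).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_t


def _truncate(time, event, cutoff):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    over = time > cutoff
    return np.where(over, cutoff, time), np.where(over, 0, event)


def _logrank_trend(time, event, labels, order) -> tuple[float, float]:
    """Log-rank test for trend across ordered groups (scores 1..k)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    k = len(order)
    scores = np.arange(1, k + 1, dtype=float)
    group_idx = np.array([order.index(l) for l in labels])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        d = int(((time == t) & (event == 1)).sum())
        if n < 2 or d == 0:
            continue
        ng = np.bincount(group_idx[at_risk], minlength=k).astype(float)
        dg = np.bincount(group_idx[(time == t) & (event == 1)], minlength=k).astype(float)
        O += dg
        E += d * ng / n
        frac = ng / n
        V += d * (n - d) / (n - 1) * (np.diag(frac) - np.outer(frac, frac))
    num = scores @ (O - E)
    den = scores @ V @ scores
    if den <= 0:
        return 0.0, 1.0
    chi2 = num**2 / den
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass
class KMResult:
    curves: dict
    logrank_chi2: float
    logrank_p: float
    trend_chi2: float | None
    trend_p: float | None
    group_sizes: dict


def km_logrank(
    groups,
    time,
    event,
    truncate_days: float | None = None,
    order: list | None = None,
) -> KMResult:
    """Kaplan-Meier curves with Mantel-Cox log-rank testing.

    With more than two groups a log-rank test for trend over the ordered
    groups (scores 1..k) is computed in addition to the overall test.
    ``truncate_days`` administratively censors follow-up at the cutoff.
    """
    labels = np.asarray(groups)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if truncate_days is not None:
        time, event = _truncate(time, event, truncate_days)
    uniq = [u for u in (order if order is not None else sorted(pd.unique(labels)))]
    sizes = {u: int((labels == u).sum()) for u in uniq}
    if len(uniq) < 2 or any(s == 0 for s in sizes.values()):
        raise ValueError("need >=2 non-empty groups")

    curves = {}
    for u in uniq:
        kmf = KaplanMeierFitter()
        m = labels == u
        kmf.fit(time[m], event[m], label=str(u))
        curves[u] = kmf.survival_function_

    if len(uniq) == 2:
        res = logrank_test(
            time[labels == uniq[0]], time[labels == uniq[1]],
            event[labels == uniq[0]], event[labels == uniq[1]],
        )
        trend_chi2 = trend_p = None
    else:
        res = multivariate_logrank_test(time, labels, event)
        trend_chi2, trend_p = _logrank_trend(time, event, labels, uniq)
    return KMResult(curves, float(res.test_statistic), float(res.p_value),
                    trend_chi2, trend_p, sizes)


@dataclass
class SurvivalFit:
    hr: float
    ci_low: float
    ci_high: float
    p: float
    threshold: float | None = None


@dataclass
class CoxResult:
    summary: pd.DataFrame
    fits: dict
    fitter: CoxPHFitter
    data: pd.DataFrame


def cox_model(
    covariates: pd.DataFrame,
    time,
    event,
    truncate_days: float | None = None,
) -> CoxResult:
    """Cox proportional-hazards fit (Efron tie handling, via lifelines).

    ``covariates`` is samples x covariates (numeric); HR = exp(coef) with
    Wald 95% CI and P per covariate. Raises on constant covariates, on
    fewer events than covariates, and on non-convergence.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if truncate_days is not None:
        time, event = _truncate(time, event, truncate_days)
    const = [c for c in covariates.columns if covariates[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariates: {const}")
    if event.sum() < covariates.shape[1]:
        raise ValueError("fewer events than covariates")
    df = covariates.copy().astype(float)
    df["time"] = time
    df["event"] = event
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise ValueError(f"Cox model failed to converge: {exc}") from exc
    summ = cph.summary
    out = pd.DataFrame(
        {
            "hr": summ["exp(coef)"],
            "ci_low": summ["exp(coef) lower 95%"],
            "ci_high": summ["exp(coef) upper 95%"],
            "p": summ["p"],
        }
    )
    fits = {
        c: SurvivalFit(out.loc[c, "hr"], out.loc[c, "ci_low"],
                       out.loc[c, "ci_high"], out.loc[c, "p"])
        for c in out.index
    }
    return CoxResult(out, fits, cph, df)


def marginal_hazard_curve(
    cox: CoxResult,
    exposure: str,
    grid,
    ref: float | None = None,
    age_col: str | None = None,
    ages=None,
) -> pd.DataFrame:
    """Marginal relative hazard across an exposure grid with a 95% band.

    The relative hazard at grid value g versus ``ref`` (default: the
    observed mean exposure) is exp((g - ref) * beta), with a delta-method
    Wald band. When the model contains an ``exposure:age`` interaction
    column (named ``f"{exposure}:{age_col}"``) and ``ages`` are given, one
    curve per age is returned.
    """
    grid = np.asarray(grid, dtype=float)
    obs = cox.data[exposure]
    if ref is None:
        ref = float(obs.mean())
    if grid.min() < obs.min() or grid.max() > obs.max():
        logger.warning("marginal_hazard_curve: grid extends outside observed exposure range")
    beta = cox.fitter.params_
    V = cox.fitter.variance_matrix_
    inter = f"{exposure}:{age_col}" if age_col is not None else None
    rows = []
    for age in (ages if ages is not None and inter in beta.index else [None]):
        b = beta[exposure] + (age * beta[inter] if age is not None else 0.0)
        var = V.loc[exposure, exposure]
        if age is not None:
            var = (
                var + 2 * age * V.loc[exposure, inter]
                + age**2 * V.loc[inter, inter]
            )
        d = grid - ref
        log_hr = d * b
        se = np.abs(d) * np.sqrt(max(var, 0.0))
        for g, lh, s in zip(grid, log_hr, se):
            rows.append(
                (age, g, np.exp(lh), np.exp(lh - 1.96 * s), np.exp(lh + 1.96 * s))
            )
    return pd.DataFrame(rows, columns=["age", "exposure", "hr", "ci_low", "ci_high"])


def ccle_stratify_essentiality(
    expr: pd.Series,
    ceres: pd.DataFrame,
    cutoff: float = 1.0,
) -> tuple[pd.Series, pd.Series]:
    """Stratify cell lines by expression and contrast CRISPR dependencies.

    Lines with log2(RPKM+1) >= ``cutoff`` are "high" (the boundary value is
    high), the rest "low". Differential essentiality per gene is
    mean CERES(high) - mean CERES(low); negative values indicate stronger
    essentiality in the high-expression lines.
    """
    shared = expr.index.intersection(ceres.index)
    if len(shared) == 0:
        raise ValueError("no shared cell lines between expression and CERES tables")
    expr = expr.loc[shared]
    ceres = ceres.loc[shared]
    groups = pd.Series(np.where(expr >= cutoff, "high", "low"), index=shared)
    if (groups == "high").sum() == 0 or (groups == "low").sum() == 0:
        raise ValueError("one expression group is empty at this cutoff")
    diff = ceres[groups == "high"].mean(axis=0) - ceres[groups == "low"].mean(axis=0)
    diff.name = "differential_essentiality"
    return groups, diff
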