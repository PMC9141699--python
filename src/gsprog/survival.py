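"""Univariate Cox proportional-hazards screening of every gene.

The gene weight used throughout the pipeline is the *signed score-test
statistic* ``z = U(0) / sqrt(I(0))`` of a univariate Cox model: the partial
likelihood score and information evaluated at ``beta = 0``, with Efron handling
of tied event times.  Positive ``z`` means higher expression, higher hazard.
The two-sided p-value is ``P(chi2_1 >= z^2)`` and the hazard ratio is
``exp(beta_hat)`` from a Newton fit of the same partial likelihood.

Score and information at ``beta = 0`` reduce to risk-set suffix sums, so the
statistic is computed for all genes (and, in the permutation machinery of the
composite-score module, all permutations) in single vectorized passes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, SurvivalTable, Transform, TransformStateError

__all__ = [
    "GeneSurvResult",
    "RankedGeneList",
    "cox_score_stats",
    "cox_fit_beta",
    "cox_univariate",
    "screen_all_genes",
    "rank_by_pvalue",
    "GeneSurvivalScreen",
    "GeneSurvivalScreenResults",
]

_METRIC_CAP = 320.0  # -log10 ceiling for p-value underflow


@dataclass(frozen=True)
class GeneSurvResult:
    gene_id: str
    score_z: float
    p_value: float
    hazard_ratio: float
    n_used: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")


@dataclass(frozen=True)
class RankedGeneList:
    """Gene ids ordered by ranking metric, descending; ties by gene id."""

    gene_ids: tuple
    metric: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "metric", np.asarray(self.metric, dtype=float))
        if len(self.gene_ids) != self.metric.shape[0]:
            raise ValueError("gene_ids and metric must have equal length")

    def __len__(self) -> int:
        return len(self.gene_ids)


# ---------------------------------------------------------------------------
# event-time structure shared by score statistics and the log-rank test


def _event_blocks(time: np.ndarray, event: np.ndarray):
    """Sort order plus, per distinct event time, the risk-set start index and
    the sorted positions of the tied deaths."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order]
    n = t.shape[0]
    blocks = []
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        deaths = np.nonzero(e[i:j] == 1)[0] + i
        if deaths.size:
            blocks.append((i, deaths))
        i = j
    return order, blocks


def _score_stats_sorted(xs: np.ndarray, blocks, n: int):
    """Efron score U(0) and information I(0) for expression already in
    survival-sorted order along the last axis.  Works for any leading shape
    (genes, or permutations x genes)."""
    rev = np.cumsum(xs[..., ::-1], axis=-1)[..., ::-1]
    rev2 = np.cumsum((xs**2)[..., ::-1], axis=-1)[..., ::-1]
    u = np.zeros(xs.shape[:-1])
    info = np.zeros(xs.shape[:-1])
    for f, deaths in blocks:
        d = deaths.size
        n_risk = n - f
        s_r = rev[..., f]
        q_r = rev2[..., f]
        xd = xs[..., deaths]
        s_d = xd.sum(axis=-1)
        q_d = (xd**2).sum(axis=-1)
        u += s_d
        for tie in range(d):
            frac = tie / d
            denom = n_risk - tie
            mean = (s_r - frac * s_d) / denom
            u -= mean
            info += (q_r - frac * q_d) / denom - mean**2
    return u, info


def cox_score_stats(X: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Score U(0) and information I(0) per gene (rows of ``X``), Efron ties."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    order, blocks = _event_blocks(time, event)
    return _score_stats_sorted(X[:, order], blocks, X.shape[1])


def _efron_ui_at_beta(x_sorted, blocks, n, beta):
    """Score and information of the Efron partial likelihood at a given beta
    for one covariate already in survival-sorted order."""
    w = np.exp(beta * x_sorted)
    xw = x_sorted * w
    x2w = x_sorted * xw
    rev_w = np.cumsum(w[::-1])[::-1]
    rev_xw = np.cumsum(xw[::-1])[::-1]
    rev_x2w = np.cumsum(x2w[::-1])[::-1]
    u = 0.0
    info = 0.0
    for f, deaths in blocks:
        d = deaths.size
        w_d = w[deaths].sum()
        xw_d = xw[deaths].sum()
        x2w_d = x2w[deaths].sum()
        u += x_sorted[deaths].sum()
        for tie in range(d):
            frac = tie / d
            denom = rev_w[f] - frac * w_d
            num = rev_xw[f] - frac * xw_d
            u -= num / denom
            info += (rev_x2w[f] - frac * x2w_d) / denom - (num / denom) ** 2
    return u, info


def cox_fit_beta(
    x: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
    beta_cap: float = 20.0,
) -> float:
    """Newton-Raphson fit of the univariate Cox coefficient (Efron ties).

    The coefficient is capped at ``+-beta_cap`` to keep the hazard ratio
    finite under monotone separation.
    """
    x = np.asarray(x, dtype=float)
    order, blocks = _event_blocks(time, event)
    xs = x[order]
    n = xs.shape[0]
    beta = 0.0
    for _ in range(max_iter):
        u, info = _efron_ui_at_beta(xs, blocks, n, beta)
        if not np.isfinite(u) or info <= 1e-12:
            break
        step = np.clip(u / info, -5.0, 5.0)
        beta += step
        if abs(beta) >= beta_cap:
            beta = float(np.clip(beta, -beta_cap, beta_cap))
            break
        if abs(step) < tol:
            break
    return float(beta)


def _score_z_p(u: np.ndarray, info: np.ndarray, eps: float = 1e-12):
    info = np.asarray(info, dtype=float)
    u = np.asarray(u, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(info > eps, u / np.sqrt(np.maximum(info, eps)), 0.0)
    p = stats.chi2.sf(z**2, df=1)
    p = np.where(info > eps, p, 1.0)
    return z, p


def cox_univariate(expr_row, surv: SurvivalTable, gene_id: str = "gene") -> GeneSurvResult:
    """Single-gene Cox screen: signed score z, chi2(1) p, fitted hazard ratio.

    Requires >= 2 observed events; a constant expression row yields the
    degenerate result (z = 0, p = 1, hazard ratio 1).
    """
    x = np.asarray(expr_row, dtype=float)
    if x.shape[0] != surv.n:
        raise ValueError("expression row and survival table lengths differ")
    if surv.n_events < 2:
        raise ValueError("at least 2 observed events are required")
    if np.ptp(x) == 0:
        return GeneSurvResult(gene_id, 0.0, 1.0, 1.0, surv.n, degenerate=True)
    u, info = cox_score_stats(x[None, :], surv.time, surv.event)
    z, p = _score_z_p(u, info)
    if info[0] <= 1e-12:
        return GeneSurvResult(gene_id, 0.0, 1.0, 1.0, surv.n, degenerate=True)
    beta = cox_fit_beta(x, surv.time, surv.event)
    return GeneSurvResult(gene_id, float(z[0]), float(p[0]), float(np.exp(beta)), surv.n)


def screen_all_genes(expr: ExpressionMatrix, surv: SurvivalTable):
    """Univariate Cox screen of every gene on the expr/surv sample intersection.

    Returns ``(results, degenerate_gene_ids)``: one :class:`GeneSurvResult`
    per non-degenerate gene in matrix order, plus the ids of genes whose row
    was constant on the intersected samples.
    """
    if expr.transform is not Transform.LOG_STANDARDIZED:
        raise TransformStateError("screen_all_genes expects a log_standardized matrix")
    surv_samples = set(surv.sample_ids)
    common = [s for s in expr.sample_ids if s in surv_samples]
    if not common:
        raise ValueError("no samples shared between expression matrix and survival table")
    sub_expr = expr.subset_samples(common)
    sub_surv = surv.subset(common)
    if sub_surv.n_events < 2:
        raise ValueError("at least 2 observed events are required")
    X = sub_expr.values
    constant = np.ptp(X, axis=1) == 0
    u, info = cox_score_stats(X, sub_surv.time, sub_surv.event)
    z, p = _score_z_p(u, info)
    degenerate = constant | (info <= 1e-12)
    results = []
    degenerate_ids = []
    for i, gene in enumerate(sub_expr.gene_ids):
        if degenerate[i]:
            degenerate_ids.append(gene)
            continue
        beta = cox_fit_beta(X[i], sub_surv.time, sub_surv.event)
        results.append(
            GeneSurvResult(gene, float(z[i]), float(p[i]), float(np.exp(beta)), len(common))
        )
    return results, degenerate_ids


def rank_by_pvalue(results, cap: float = _METRIC_CAP) -> RankedGeneList:
    """Rank genes by ``-log10(p)`` descending (significant end on top).

    Ties break lexicographically by gene id; p-value underflow is capped so
    the metric stays finite.
    """
    if not results:
        raise ValueError("cannot rank an empty result list")
    genes = [r.gene_id for r in results]
    p = np.array([r.p_value for r in results], dtype=float)
    with np.errstate(divide="ignore"):
        metric = np.minimum(-np.log10(np.maximum(p, 0.0)), cap)
    metric[p == 0] = cap
    order = sorted(range(len(genes)), key=lambda i: (-metric[i], genes[i]))
    return RankedGeneList(tuple(genes[i] for i in order), metric[order])


# ---------------------------------------------------------------------------
# model / results surface


class GeneSurvivalScreen:
    """Univariate Cox screen of every gene against right-censored survival.

    Parameters
    ----------
    expr
        Expression matrix; a raw matrix is log-standardized internally.
    surv
        Survival table; samples are intersected with the matrix.
    min_mean
        Optional raw-scale mean-expression filter applied before
        standardization (off by default).
    """

    def __init__(self, expr: ExpressionMatrix, surv: SurvivalTable, min_mean: float | None = None):
        from .io import log_standardize

        if expr.transform is Transform.RAW:
            if min_mean is not None:
                keep = expr.values.mean(axis=1) >= min_mean
                expr = expr.subset_genes(
                    [g for g, k in zip(expr.gene_ids, keep) if k]
                )
            expr = log_standardize(expr)
        elif min_mean is not None:
            raise TransformStateError("min_mean filter requires a raw matrix")
        self.expr = expr
        self.surv = surv

    def fit(self) -> "GeneSurvivalScreenResults":
        results, degenerate = screen_all_genes(self.expr, self.surv)
        return GeneSurvivalScreenResults(self, results, degenerate)


class GeneSurvivalScreenResults:
    """Per-gene score statistics, p-values and hazard ratios from the screen."""

    def __init__(self, model: GeneSurvivalScreen, results, degenerate_gene_ids):
        self.model = model
        self.results = list(results)
        self.degenerate_gene_ids = list(degenerate_gene_ids)

    @property
    def frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": r.gene_id,
                "score_z": r.score_z,
                "p_value": r.p_value,
                "hazard_ratio": r.hazard_ratio,
                "n_used": r.n_used,
                "degenerate": r.degenerate,
            }
            for r in self.results
        ]
        rows += [
            {
                "gene_id": g,
                "score_z": 0.0,
                "p_value": 1.0,
                "hazard_ratio": 1.0,
                "n_used": 0,
                "degenerate": True,
            }
            for g in self.degenerate_gene_ids
        ]
        return pd.DataFrame(rows)

    def ranked(self, cap: float = _METRIC_CAP) -> RankedGeneList:
        return rank_by_pvalue(self.results, cap=cap)

    def significant(self, alpha: float = 0.05):
        return [r for r in self.results if r.p_value < alpha]

    def summary(self, alpha: float = 0.05) -> str:
        n_sig = len(self.significant(alpha))
        lines = [
            "Univariate Cox gene survival screen",
            "=" * 44,
            f"genes screened:        {len(self.results)}",
            f"degenerate (constant): {len(self.degenerate_gene_ids)}",
            f"significant at {alpha:g}:   {n_sig}",
        ]
        top = sorted(self.results, key=lambda r: (r.p_value, r.gene_id))[:10]
        lines.append("-" * 44)
        lines.append(f"{'gene':<14}{'z':>8}{'p':>12}{'HR':>8}")
        for r in top:
            lines.append(f"{r.gene_id:<14}{r.score_z:>8.3f}{r.p_value:>12.3e}{r.hazard_ratio:>8.3f}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)
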