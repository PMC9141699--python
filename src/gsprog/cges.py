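"""Composite Gene Expression Score (CGES) gene-set survival testing.

For a k-gene set the per-patient surrogate expression value is

    CGES = 1 / (1 + exp(-(sum_i beta_i * x_i - m)))

where ``x_i`` is the standardized log-transformed expression of gene *i*,
``beta_i`` is that gene's signed Cox score-test statistic from the univariate
survival screen, and ``m`` is the median of the linear combination across the
training patients.  Patients are scored by leave-one-out cross-validation
(weights and ``m`` refit without the held-out patient, to correct for the
supervision in the weights), dichotomized at the median CGES, and compared by
the two-group log-rank test.  Significance comes from an outcome-permutation
null: (time, event) pairs are permuted jointly across patients, the weights
are refit on each permuted outcome, and the whole score/split/log-rank
pipeline is recomputed.  The permutation p-value is the plain exceedance
fraction ``#(chi2_perm >= chi2_obs) / n_perm`` — zero is attainable, and sets
tied at zero are ranked by the z-score of the observed statistic against the
permutation null.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import ExpressionMatrix, GeneSet, GeneSetCollection, SurvivalTable, Transform, TransformStateError
from .survival import _event_blocks, _score_stats_sorted, cox_fit_beta, cox_score_stats

logger = logging.getLogger(__name__)

__all__ = [
    "CgesWeights",
    "CgesResult",
    "compute_weights",
    "cges_score",
    "loocv_cges",
    "logrank_chi2",
    "cges_permutation_test",
    "rank_significant_sets",
    "CGESModel",
    "CGESResults",
]


@dataclass(frozen=True)
class CgesWeights:
    """Gene weights (signed Cox score z) and the median normalization factor."""

    gene_ids: tuple
    beta: np.ndarray
    m: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        if len(self.gene_ids) < 1:
            raise ValueError("CgesWeights requires at least one gene")
        if self.beta.shape != (len(self.gene_ids),):
            raise ValueError("beta must align with gene_ids")

    @classmethod
    def from_training(cls, gene_ids, beta, x_train: np.ndarray) -> "CgesWeights":
        """Construct with ``m`` asserted to be the median of the training
        linear combination."""
        beta = np.asarray(beta, dtype=float)
        linear = beta @ np.asarray(x_train, dtype=float)
        return cls(tuple(gene_ids), beta, float(np.median(linear)))


@dataclass(frozen=True)
class CgesResult:
    set_name: str
    chi2_obs: float
    p_perm: float
    z_score: float
    hazard_ratio: float
    n_perm: int
    seed: int | None
    n_genes_used: int = 0
    perm_mean: float = float("nan")
    perm_sd: float = float("nan")
    z_defined: bool = True

    def __post_init__(self) -> None:
        if self.chi2_obs < 0:
            raise ValueError("chi2_obs must be non-negative")
        if not (0.0 <= self.p_perm <= 1.0):
            raise ValueError("p_perm must lie in [0, 1]")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")


def compute_weights(X: np.ndarray, gene_ids, time, event) -> CgesWeights:
    """Weights for one training cohort: per-gene signed score z and the
    median of the resulting linear combination."""
    u, info = cox_score_stats(X, time, event)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(info > 1e-12, u / np.sqrt(np.maximum(info, 1e-12)), 0.0)
    return CgesWeights.from_training(gene_ids, beta, X)


def cges_score(expr_subset, weights: CgesWeights) -> np.ndarray:
    """Per-patient composite score ``expit(sum beta_i x_i - m)``, in (0, 1)."""
    if isinstance(expr_subset, ExpressionMatrix):
        missing = [g for g in weights.gene_ids if g not in expr_subset.data.index]
        extra = [g for g in expr_subset.gene_ids if g not in set(weights.gene_ids)]
        if missing or extra:
            raise ValueError(
                f"gene mismatch between weights and matrix; missing={missing} extra={extra}"
            )
        X = expr_subset.data.loc[list(weights.gene_ids)].to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(expr_subset, dtype=float))
        if X.shape[0] != len(weights.gene_ids):
            raise ValueError(
                f"expected {len(weights.gene_ids)} gene rows, got {X.shape[0]}"
            )
    return expit(weights.beta @ X - weights.m)


def _align(expr: ExpressionMatrix, surv: SurvivalTable, gene_set: GeneSet):
    if expr.transform is not Transform.LOG_STANDARDIZED:
        raise TransformStateError("CGES expects a log_standardized matrix")
    surv_samples = set(surv.sample_ids)
    common = [s for s in expr.sample_ids if s in surv_samples]
    if not common:
        raise ValueError("no samples shared between expression matrix and survival table")
    genes = [g for g in gene_set.genes if g in expr.data.index and g not in expr.constant_genes]
    if not genes:
        raise ValueError(f"set {gene_set.name!r}: no member genes present in the matrix")
    X = expr.data.loc[genes, common].to_numpy(dtype=float)
    return X, genes, surv.subset(common)


def loocv_cges(expr: ExpressionMatrix, surv: SurvivalTable, gene_set: GeneSet):
    """Leave-one-out cross-validated CGES per patient.

    For each patient the gene weights and the normalization median are refit
    on the remaining n-1 patients, then the held-out patient is scored.  Folds
    with fewer than 2 events impute 0.5 (logged).  Returns
    ``(scores, flagged_fold_mask, sample_ids)``.
    """
    X, genes, surv_sub = _align(expr, surv, gene_set)
    n = surv_sub.n
    if n < 10:
        raise ValueError("LOOCV requires at least 10 patients")
    scores = np.empty(n)
    flagged = np.zeros(n, dtype=bool)
    mask = np.ones(n, dtype=bool)
    for j in range(n):
        mask[j] = False
        if surv_sub.event[mask].sum() < 2:
            scores[j] = 0.5
            flagged[j] = True
        else:
            w = compute_weights(X[:, mask], genes, surv_sub.time[mask], surv_sub.event[mask])
            scores[j] = float(cges_score(X[:, j : j + 1], w)[0])
        mask[j] = True
    if flagged.any():
        logger.info("loocv_cges: %d folds had < 2 events; imputed 0.5", int(flagged.sum()))
    return scores, flagged, surv_sub.sample_ids


# ---------------------------------------------------------------------------
# log-rank


def _logrank_many(groups_sorted: np.ndarray, blocks, n: int) -> np.ndarray:
    """Two-group log-rank chi-square, vectorized over rows of a boolean
    group-membership matrix already in survival-sorted order."""
    g = groups_sorted.astype(float)
    rev = np.cumsum(g[:, ::-1], axis=1)[:, ::-1]
    oe = np.zeros(g.shape[0])
    var = np.zeros(g.shape[0])
    for f, deaths in blocks:
        n_risk = n - f
        d = deaths.size
        n1 = rev[:, f]
        d1 = g[:, deaths].sum(axis=1)
        frac = n1 / n_risk
        oe += d1 - d * frac
        if n_risk > 1:
            var += d * frac * (1.0 - frac) * (n_risk - d) / (n_risk - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(var > 0, oe**2 / var, 0.0)
    return chi2


def logrank_chi2(groups, surv: SurvivalTable) -> float:
    """Standard two-group log-rank chi-square, (O-E)^2 / V form."""
    groups = np.asarray(groups, dtype=bool)
    if groups.shape[0] != surv.n:
        raise ValueError("group vector and survival table lengths differ")
    if groups.all() or (~groups).all():
        raise ValueError("both groups must be non-empty")
    if surv.n_events < 1:
        raise ValueError("at least one event is required")
    order, blocks = _event_blocks(surv.time, surv.event)
    return float(_logrank_many(groups[order][None, :], blocks, surv.n)[0])


# ---------------------------------------------------------------------------
# permutation test


def _median_split(scores: np.ndarray) -> np.ndarray:
    return scores > np.median(scores)


def _observed_chi2(scores: np.ndarray, surv: SurvivalTable):
    groups = _median_split(scores)
    if groups.all() or (~groups).all():
        logger.warning("degenerate median split (all scores equal); chi2_obs = 0")
        return 0.0, groups
    return logrank_chi2(groups, surv), groups


def _null_chi2_refit(X, time, event, n_perm, rng, chunk_elems=4_000_000):
    """Permutation-null log-rank statistics with full weight refit per
    permutation: outcomes permuted against fixed expression, weights refit,
    all patients scored, median split, log-rank.  Vectorized over
    permutations in memory-bounded chunks."""
    k, n = X.shape
    order, blocks = _event_blocks(time, event)
    chunk = max(1, int(chunk_elems // max(1, k * n)))
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        p = min(chunk, n_perm - done)
        perms = np.stack([rng.permutation(n) for _ in range(p)])  # pi: surv_p[j] = surv[pi[j]]
        inv = np.argsort(perms, axis=1)
        js = inv[:, order]  # patients in permuted-survival-sorted order
        xs = X[:, js]  # (k, p, n)
        u, info = _score_stats_sorted(xs.transpose(1, 0, 2), blocks, n)  # (p, k)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(info > 1e-12, u / np.sqrt(np.maximum(info, 1e-12)), 0.0)
        linear = beta @ X  # (p, n) in patient order
        groups = linear > np.median(linear, axis=1, keepdims=True)
        groups_sorted = np.take_along_axis(groups, js, axis=1)
        out[done : done + p] = _logrank_many(groups_sorted, blocks, n)
        done += p
    return out


def _null_chi2_strict(X, genes, time, event, n_perm, rng):
    """Fully nested null: LOOCV repeated inside every permutation."""
    n = X.shape[1]
    out = np.empty(n_perm)
    mask = np.ones(n, dtype=bool)
    for p in range(n_perm):
        pi = rng.permutation(n)
        t_p, e_p = time[pi], event[pi]
        scores = np.empty(n)
        for j in range(n):
            mask[j] = False
            if e_p[mask].sum() < 2:
                scores[j] = 0.5
            else:
                w = compute_weights(X[:, mask], genes, t_p[mask], e_p[mask])
                scores[j] = float(cges_score(X[:, j : j + 1], w)[0])
            mask[j] = True
        groups = _median_split(scores)
        if groups.all() or (~groups).all():
            out[p] = 0.0
        else:
            order, blocks = _event_blocks(t_p, e_p)
            out[p] = _logrank_many(groups[order][None, :], blocks, n)[0]
    return out


def cges_permutation_test(
    expr: ExpressionMatrix,
    surv: SurvivalTable,
    gene_set: GeneSet,
    n_perm: int = 1000,
    seed: int | None = 0,
    strict_null: bool = False,
) -> CgesResult:
    """CGES permutation survival test for one gene set.

    The observed statistic is the log-rank chi-square of the median split of
    LOOCV scores.  The null permutes (time, event) pairs jointly across
    patients and refits the supervised weights on every permuted outcome
    (full-data refit by default; ``strict_null`` nests the LOOCV inside each
    permutation).  ``p_perm`` is the plain exceedance fraction — zero is
    attainable — and ``z_score`` locates the observed statistic in the
    permutation null.  The hazard ratio is a univariate Cox fit of survival
    on the high-vs-low CGES group indicator.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    X, genes, surv_sub = _align(expr, surv, gene_set)
    scores, _, _ = loocv_cges(expr, surv, gene_set)
    chi2_obs, groups = _observed_chi2(scores, surv_sub)
    rng = np.random.default_rng(seed)
    if strict_null:
        null = _null_chi2_strict(X, genes, surv_sub.time, surv_sub.event, n_perm, rng)
    else:
        null = _null_chi2_refit(X, surv_sub.time, surv_sub.event, n_perm, rng)
    p_perm = float(np.count_nonzero(null >= chi2_obs)) / n_perm
    perm_mean = float(null.mean())
    perm_sd = float(null.std(ddof=1)) if n_perm > 1 else 0.0
    z_defined = perm_sd > 0
    z_score = (chi2_obs - perm_mean) / perm_sd if z_defined else float("nan")
    if groups.any() and (~groups).any():
        beta = cox_fit_beta(groups.astype(float), surv_sub.time, surv_sub.event)
        hazard_ratio = float(np.exp(beta))
    else:
        hazard_ratio = 1.0
    return CgesResult(
        set_name=gene_set.name,
        chi2_obs=float(chi2_obs),
        p_perm=p_perm,
        z_score=float(z_score),
        hazard_ratio=hazard_ratio,
        n_perm=n_perm,
        seed=seed,
        n_genes_used=len(genes),
        perm_mean=perm_mean,
        perm_sd=perm_sd,
        z_defined=z_defined,
    )


def rank_significant_sets(results, alpha: float = 0.05):
    """Keep sets with ``p_perm < alpha``; order by p ascending, then z-score
    descending (the tie-ranking for exact-zero p-values), then set name."""
    if not results:
        raise ValueError("no CGES results to rank")

    def key(r: CgesResult):
        z = r.z_score if np.isfinite(r.z_score) else -np.inf
        return (r.p_perm, -z, r.set_name)

    return sorted((r for r in results if r.p_perm < alpha), key=key)


# ---------------------------------------------------------------------------
# model / results surface


class CGESModel:
    """Gene-set survival model: composite-score permutation test per set.

    Parameters
    ----------
    expr
        Expression matrix (raw matrices are log-standardized internally).
    surv
        Survival table.
    sets
        A :class:`GeneSetCollection`, a single :class:`GeneSet`, or an
        iterable of gene sets (e.g. the GSEA-selected candidates).
    """

    def __init__(self, expr: ExpressionMatrix, surv: SurvivalTable, sets):
        from .io import log_standardize

        if expr.transform is Transform.RAW:
            expr = log_standardize(expr)
        self.expr = expr
        self.surv = surv
        if isinstance(sets, GeneSet):
            sets = [sets]
        self.sets = list(sets)

    def fit(self, n_perm: int = 1000, seed: int | None = 0, strict_null: bool = False) -> "CGESResults":
        rng = np.random.default_rng(seed)
        results = []
        skipped = []
        for gene_set in self.sets:
            set_seed = int(rng.integers(0, 2**31 - 1))
            try:
                results.append(
                    cges_permutation_test(
                        self.expr, self.surv, gene_set, n_perm=n_perm, seed=set_seed,
                        strict_null=strict_null,
                    )
                )
            except ValueError as exc:
                logger.info("set %s skipped: %s", gene_set.name, exc)
                skipped.append((gene_set.name, str(exc)))
        return CGESResults(self, results, skipped, n_perm=n_perm, seed=seed)


class CGESResults:
    """Per-set permutation test results with z-score tie ranking for exact-zero p."""

    def __init__(self, model: CGESModel, results, skipped, n_perm: int, seed):
        self.model = model
        self.results = list(results)
        self.skipped = list(skipped)
        self.n_perm = n_perm
        self.seed = seed

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "set_name": r.set_name,
                    "n_genes_used": r.n_genes_used,
                    "chi2_obs": r.chi2_obs,
                    "p_perm": r.p_perm,
                    "z_score": r.z_score,
                    "hazard_ratio": r.hazard_ratio,
                }
                for r in self.results
            ]
        )

    def significant(self, alpha: float = 0.05):
        return rank_significant_sets(self.results, alpha=alpha)

    def summary(self, alpha: float = 0.05) -> str:
        sig = self.significant(alpha) if self.results else []
        lines = [
            "Composite Gene Expression Score survival test",
            "=" * 56,
            f"gene sets tested:      {len(self.results)}",
            f"skipped:               {len(self.skipped)}",
            f"permutations per set:  {self.n_perm}",
            f"significant at {alpha:g}:    {len(sig)}",
            "-" * 56,
            f"{'set':<26}{'chi2':>8}{'p_perm':>9}{'z':>7}{'HR':>7}",
        ]
        for r in sig[:15]:
            lines.append(
                f"{r.set_name[:25]:<26}{r.chi2_obs:>8.2f}{r.p_perm:>9.4f}"
                f"{r.z_score:>7.2f}{r.hazard_ratio:>7.2f}"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def permutation_summaries(self) -> dict:
        return {
            r.set_name: {"perm_mean": r.perm_mean, "perm_sd": r.perm_sd, "n_perm": r.n_perm}
            for r in self.results
        }
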