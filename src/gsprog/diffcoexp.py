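"""Differential coexpression corroboration of prognostic gene sets.

Three layers, mirroring the meta-analysis workflow around a gene-set rewiring
statistic:

* **Rewiring statistic** — per dataset and gene set, the L1 distance between
  the dominant-eigenvector gene weight vectors of the tumor and normal
  absolute-correlation matrices (unit diagonal zeroed); significance by
  permuting condition labels over the pooled samples.
* **Meta pooling** — per-dataset permutation exceedance proportions pooled on
  the logit scale with a random-effects model (REML between-dataset
  variance); nonparametric confidence intervals and a bootstrap p by
  resampling datasets with replacement.
* **Link classification** — per gene pair, Pearson correlations in each
  condition; pairs whose absolute log correlation ratio exceeds a rolling
  empirical-quantile boundary (as a function of the maximum coexpression) are
  differentially coexpressed, classed strengthened or weakened.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit, logit

from .io import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "PairedDataset",
    "DiffCoexpRecord",
    "MetaResult",
    "Link",
    "LinkSet",
    "gsnca_w_dist",
    "gsnca_permutation_p",
    "meta_pool",
    "dce_links",
]

MIN_SAMPLES_PER_CONDITION = 5


@dataclass(frozen=True)
class PairedDataset:
    """Tumor and normal expression over a shared gene universe; samples need
    not pair one-to-one."""

    dataset_id: str
    tumor: ExpressionMatrix
    normal: ExpressionMatrix


@dataclass(frozen=True)
class DiffCoexpRecord:
    set_name: str
    dataset_id: str
    w_dist: float
    p_perm: float
    n_perm: int
    n_exceed: int

    def __post_init__(self) -> None:
        if self.w_dist < 0:
            raise ValueError("w_dist must be non-negative")
        if not (0.0 <= self.p_perm <= 1.0):
            raise ValueError("p_perm must lie in [0, 1]")


@dataclass(frozen=True)
class MetaResult:
    set_name: str
    pooled_prop: float
    ci_low: float
    ci_high: float
    boot_p: float
    n_datasets: int
    tau2: float = 0.0

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.pooled_prop <= self.ci_high):
            raise ValueError("CI must bracket the pooled proportion")


@dataclass(frozen=True)
class Link:
    gene_a: str
    gene_b: str
    r_normal: float
    r_tumor: float
    link_class: str  # "strengthened" | "weakened"

    def __post_init__(self) -> None:
        if not self.gene_a < self.gene_b:
            raise ValueError("links must be in canonical gene_a < gene_b order")
        expected = "strengthened" if abs(self.r_tumor) > abs(self.r_normal) else "weakened"
        if self.link_class != expected:
            raise ValueError(f"link class inconsistent with correlations: {self}")


@dataclass(frozen=True)
class LinkSet:
    links: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "links", tuple(self.links))
        pairs = [(l.gene_a, l.gene_b) for l in self.links]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate gene pairs in link set")

    def __len__(self) -> int:
        return len(self.links)

    def __iter__(self):
        return iter(self.links)

    def of_class(self, link_class: str) -> "LinkSet":
        return LinkSet(tuple(l for l in self.links if l.link_class == link_class))


# ---------------------------------------------------------------------------
# rewiring statistic


def _dominant_weights(abs_corr: np.ndarray) -> np.ndarray:
    """Non-negative, L1-normalized dominant eigenvector of an
    absolute-correlation matrix with the unit diagonal zeroed."""
    a = np.array(abs_corr, dtype=float, copy=True)
    np.fill_diagonal(a, 0.0)
    eigvals, eigvecs = np.linalg.eigh(a)
    w = eigvecs[:, -1]
    # Perron vector of a non-negative matrix: fix the sign, clear round-off
    if w.sum() < 0:
        w = -w
    w = np.clip(w, 0.0, None)
    total = w.sum()
    if total == 0:  # zero matrix: uniform weights
        return np.full(a.shape[0], 1.0 / a.shape[0])
    return w / total


def gsnca_w_dist(tumor_corr: np.ndarray, normal_corr: np.ndarray) -> float:
    """Gene-gene rewiring statistic: L1 distance between the dominant
    eigenvector weight vectors of two absolute-correlation matrices."""
    t = np.asarray(tumor_corr, dtype=float)
    n = np.asarray(normal_corr, dtype=float)
    for name, mat in (("tumor", t), ("normal", n)):
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
            raise ValueError(f"{name} correlation matrix must be square")
        if mat.shape[0] < 3:
            raise ValueError("rewiring statistic requires at least 3 genes")
        if not np.allclose(mat, mat.T, atol=1e-10):
            raise ValueError(f"{name} correlation matrix must be symmetric")
    if t.shape != n.shape:
        raise ValueError("correlation matrices must have equal shape")
    return float(np.abs(_dominant_weights(t) - _dominant_weights(n)).sum())


def _abs_corr(values: np.ndarray) -> np.ndarray:
    return np.abs(np.corrcoef(values))


def _set_values(matrix: ExpressionMatrix, genes) -> np.ndarray:
    present = [g for g in genes if g in matrix.data.index]
    return matrix.data.loc[present].to_numpy(dtype=float)


def gsnca_permutation_p(
    paired: PairedDataset,
    gene_set: GeneSet,
    n_perm: int = 100,
    seed: int | None = 0,
) -> DiffCoexpRecord | None:
    """Permutation p for the rewiring statistic of one set in one dataset.

    The null permutes condition labels over the pooled samples and recomputes
    both correlation matrices;
    ``p = (#{w_null >= w_obs} + 1) / (n_perm + 1)``.  Returns ``None`` (with a
    logged reason) when the set or the sample counts are insufficient.
    """
    genes = [
        g
        for g in gene_set.genes
        if g in paired.tumor.data.index and g in paired.normal.data.index
    ]
    if len(genes) < 3:
        logger.info(
            "set %s skipped in %s: <3 genes shared by both conditions",
            gene_set.name, paired.dataset_id,
        )
        return None
    xt = _set_values(paired.tumor, genes)
    xn = _set_values(paired.normal, genes)
    n_t, n_n = xt.shape[1], xn.shape[1]
    if min(n_t, n_n) < MIN_SAMPLES_PER_CONDITION:
        logger.info(
            "set %s skipped in %s: <%d samples in a condition",
            gene_set.name, paired.dataset_id, MIN_SAMPLES_PER_CONDITION,
        )
        return None
    w_obs = gsnca_w_dist(_abs_corr(xt), _abs_corr(xn))
    pooled = np.concatenate([xt, xn], axis=1)
    rng = np.random.default_rng(seed)
    n_exceed = 0
    for _ in range(n_perm):
        idx = rng.permutation(n_t + n_n)
        w_null = gsnca_w_dist(
            _abs_corr(pooled[:, idx[:n_t]]), _abs_corr(pooled[:, idx[n_t:]])
        )
        if w_null >= w_obs:
            n_exceed += 1
    p = (n_exceed + 1) / (n_perm + 1)
    return DiffCoexpRecord(gene_set.name, paired.dataset_id, w_obs, p, n_perm, n_exceed)


# ---------------------------------------------------------------------------
# random-effects meta pooling


def _reml_tau2(y: np.ndarray, v: np.ndarray) -> float:
    """REML estimate of the between-dataset variance on the logit scale."""
    if y.shape[0] < 2:
        return 0.0

    def neg_restricted_ll(tau2):
        w = 1.0 / (v + tau2)
        mu = np.sum(w * y) / np.sum(w)
        return 0.5 * (
            np.sum(np.log(v + tau2)) + np.log(np.sum(w)) + np.sum(w * (y - mu) ** 2)
        )

    upper = max(10.0 * float(np.var(y)), 1.0)
    res = minimize_scalar(neg_restricted_ll, bounds=(0.0, upper), method="bounded")
    return float(res.x)


def _pool_logit(y: np.ndarray, v: np.ndarray, tau2: float | None):
    if tau2 is None:
        tau2 = _reml_tau2(y, v)
    w = 1.0 / (v + tau2)
    return float(np.sum(w * y) / np.sum(w)), tau2


def meta_pool(
    records,
    n_boot: int = 100,
    seed: int | None = 0,
    null_prop: float = 0.5,
    tau2: float | None = None,
) -> MetaResult:
    """Random-effects pooling of per-dataset permutation-exceedance
    proportions for one gene set.

    Each record's exceedance count is treated as a binomial proportion,
    continuity-corrected by 0.5 and pooled on the logit scale with a REML
    between-dataset variance (``tau2`` may be pinned, e.g. to 0, for the
    fixed-effect limit).  The confidence interval comes from resampling
    datasets with replacement.  ``boot_p`` is a one-sided bootstrap test of
    collective differential coexpression: the fraction of bootstrap pooled
    proportions at or above ``null_prop``, the chance level of a permutation
    exceedance proportion (0.5).  A set whose rewiring statistic consistently
    beats its permutation null across the panel drives ``boot_p`` toward 0;
    the significance claim is ``boot_p < 0.05``.
    """
    records = [r for r in records if r.n_perm > 0]
    if len(records) < 2:
        raise ValueError("meta pooling requires records from at least 2 datasets")
    names = {r.set_name for r in records}
    if len(names) != 1:
        raise ValueError(f"records must concern a single gene set, got {sorted(names)}")
    x = np.array([r.n_exceed for r in records], dtype=float)
    n = np.array([r.n_perm for r in records], dtype=float)
    p_tilde = (x + 0.5) / (n + 1.0)
    y = logit(p_tilde)
    v = 1.0 / (x + 0.5) + 1.0 / (n - x + 0.5)
    pooled_logit, tau2_hat = _pool_logit(y, v, tau2)
    pooled = float(expit(pooled_logit))
    rng = np.random.default_rng(seed)
    k = len(records)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, k, size=k)
        yb, vb = y[idx], v[idx]
        bl, _ = _pool_logit(yb, vb, tau2)
        boots[b] = expit(bl)
    ci_low = float(np.quantile(boots, 0.025))
    ci_high = float(np.quantile(boots, 0.975))
    ci_low, ci_high = min(ci_low, pooled), max(ci_high, pooled)
    boot_p = (float(np.count_nonzero(boots >= null_prop)) + 1.0) / (n_boot + 1.0)
    return MetaResult(records[0].set_name, pooled, ci_low, ci_high, boot_p, k, tau2_hat)


# ---------------------------------------------------------------------------
# differential links


def dce_links(
    paired: PairedDataset,
    gene_universe,
    q_outlier: float = 0.01,
    eps: float = 1e-3,
    bin_width: float = 0.1,
) -> LinkSet:
    """Classify differentially coexpressed gene pairs in one dataset.

    For every canonical gene pair, ``M = max(|r_normal|, |r_tumor|)`` and
    ``L = log(|r_tumor| / |r_normal|)`` (epsilon floor on both magnitudes).
    The boundary curve is the rolling ``1 - q_outlier`` empirical quantile of
    ``|L|`` across ``M`` bins; pairs above it are differentially coexpressed,
    strengthened when ``|r_tumor| > |r_normal|`` else weakened.  Links
    touching a constant gene are skipped.
    """
    if not (0.0 < q_outlier < 1.0):
        raise ValueError("q_outlier must lie in (0, 1)")
    genes = [
        g
        for g in gene_universe
        if g in paired.tumor.data.index and g in paired.normal.data.index
    ]
    genes = sorted(set(genes))
    if len(genes) < 2:
        return LinkSet(())
    xt = paired.tumor.data.loc[genes].to_numpy(dtype=float)
    xn = paired.normal.data.loc[genes].to_numpy(dtype=float)
    if min(xt.shape[1], xn.shape[1]) < MIN_SAMPLES_PER_CONDITION:
        raise ValueError("both conditions need >= 5 samples for correlations")
    ok = (np.ptp(xt, axis=1) > 0) & (np.ptp(xn, axis=1) > 0)
    if not ok.all():
        logger.info("dce_links: skipped %d constant genes", int((~ok).sum()))
    genes = [g for g, keep in zip(genes, ok) if keep]
    if len(genes) < 2:
        return LinkSet(())
    rt = np.corrcoef(xt[ok])
    rn = np.corrcoef(xn[ok])
    iu, ju = np.triu_indices(len(genes), k=1)
    r_t = rt[iu, ju]
    r_n = rn[iu, ju]
    m_val = np.maximum(np.abs(r_n), np.abs(r_t))
    l_val = np.log(np.maximum(np.abs(r_t), eps) / np.maximum(np.abs(r_n), eps))
    abs_l = np.abs(l_val)
    bins = np.floor(m_val / bin_width).astype(int)
    # sparse bins cannot support a quantile boundary: widen each bin
    # symmetrically until it holds enough pairs
    min_bin_count = min(10, abs_l.shape[0])
    boundary = np.empty_like(abs_l)
    for b in np.unique(bins):
        in_bin = bins == b
        width = 0
        while in_bin.sum() < min_bin_count:
            width += 1
            in_bin = np.abs(bins - b) <= width
        boundary[bins == b] = np.quantile(abs_l[in_bin], 1.0 - q_outlier)
    flagged = abs_l > boundary
    links = []
    for idx in np.nonzero(flagged)[0]:
        a, b = genes[iu[idx]], genes[ju[idx]]
        cls = "strengthened" if abs(r_t[idx]) > abs(r_n[idx]) else "weakened"
        links.append(Link(a, b, float(r_n[idx]), float(r_t[idx]), cls))
    return LinkSet(tuple(links))


def merge_link_sets(link_sets) -> LinkSet:
    """Union of links across datasets (canonical pairs deduplicated; the
    first occurrence's correlations are kept, class must agree or the link is
    dropped as ambiguous)."""
    seen = {}
    dropped = 0
    for ls in link_sets:
        for link in ls:
            key = (link.gene_a, link.gene_b)
            if key not in seen:
                seen[key] = link
            elif seen[key].link_class != link.link_class:
                dropped += 1
                seen[key] = None
    if dropped:
        logger.info("merge_link_sets: dropped %d class-ambiguous pairs", dropped)
    return LinkSet(tuple(l for l in seen.values() if l is not None))
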