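"""Gene-set crosstalk networks.

Two constructions, kept in separate runs so a network represents either
enhanced or attenuated coordination but never both:

* **Cross-link enrichment** — for each pair of gene sets, the observed count
  of differentially coexpressed links crossing between them is tested against
  a hypergeometric null (drawing that many links from all possible
  cross-universe pairs).  Genes shared by both sets are excluded from the
  cross-count so overlap-driven edges cannot masquerade as crosstalk.
* **Profile similarity** — gene sets whose differential-coexpression
  significance profiles across the dataset panel correlate positively; edge
  significance by permuting dataset labels.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffcoexp import LinkSet
from .io import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "CrosstalkEdge",
    "cspn_edges",
    "profile_similarity_edges",
    "export_network",
    "read_network_tsv",
]

MODES = ("profile_similarity", "weakened_links", "strengthened_links")


@dataclass(frozen=True)
class CrosstalkEdge:
    set_a: str
    set_b: str
    statistic: float
    p_value: float
    mode: str

    def __post_init__(self) -> None:
        if not self.set_a < self.set_b:
            raise ValueError("edges must be in canonical set_a < set_b order")
        if self.mode not in MODES:
            raise ValueError(f"unknown edge mode {self.mode!r}")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def cspn_edges(links: LinkSet, sets: GeneSetCollection, alpha: float = 0.05):
    """Set-set edges where cross-set differential links are hypergeometrically
    enriched.

    The universe is every unordered gene pair over the union of set members;
    the observed links (restricted to that universe) are the draw.  For a set
    pair, successes are the pairs crossing between the two sets' exclusive
    members (shared genes excluded); the edge p-value is the upper
    hypergeometric tail of the observed cross-link count.
    """
    classes = {l.link_class for l in links}
    if len(classes) > 1:
        raise ValueError("links must all belong to a single class")
    mode = f"{classes.pop()}_links" if classes else "weakened_links"
    universe = sorted({g for s in sets for g in s.genes})
    uset = set(universe)
    n_pairs_total = math.comb(len(universe), 2)
    link_pairs = {
        (l.gene_a, l.gene_b) for l in links if l.gene_a in uset and l.gene_b in uset
    }
    n_links = len(link_pairs)
    if n_links == 0:
        logger.info("cspn_edges: no links within the set universe; empty network")
        return []
    edges = []
    ordered = sorted(sets, key=lambda s: s.name)
    for i, sa in enumerate(ordered):
        for sb in ordered[i + 1 :]:
            a_excl = set(sa.genes) - set(sb.genes)
            b_excl = set(sb.genes) - set(sa.genes)
            n_cross_possible = len(a_excl) * len(b_excl)
            if n_cross_possible == 0:
                continue
            k = sum(
                1
                for (ga, gb) in link_pairs
                if (ga in a_excl and gb in b_excl) or (ga in b_excl and gb in a_excl)
            )
            if k == 0:
                continue
            p = float(stats.hypergeom.sf(k - 1, n_pairs_total, n_cross_possible, n_links))
            if p < alpha:
                a, b = sorted([sa.name, sb.name])
                edges.append(CrosstalkEdge(a, b, float(k), p, mode))
    return edges


def profile_similarity_edges(
    profiles: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = 0,
):
    """Set-set edges from the similarity of differential-coexpression
    significance profiles across the dataset panel.

    ``profiles`` is a sets x datasets frame of p-values.  Similarity is the
    Pearson correlation of the ``-log10 p`` profiles; significance is
    one-tailed (positive similarity) by permuting dataset labels.  Constant
    profiles are skipped (logged).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    logp = -np.log10(np.clip(profiles.to_numpy(dtype=float), 1e-300, 1.0))
    names = list(profiles.index)
    n_ds = logp.shape[1]
    if n_ds < 3:
        raise ValueError("profile similarity requires at least 3 datasets")
    rng = np.random.default_rng(seed)
    edges = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = logp[i], logp[j]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                logger.info(
                    "profile pair (%s, %s) skipped: constant profile", names[i], names[j]
                )
                continue
            r_obs = float(np.corrcoef(a, b)[0, 1])
            count = 0
            for _ in range(n_perm):
                r_null = float(np.corrcoef(a, b[rng.permutation(n_ds)])[0, 1])
                if r_null >= r_obs:
                    count += 1
            p = (count + 1) / (n_perm + 1)
            if p < alpha:
                sa, sb = sorted([names[i], names[j]])
                edges.append(CrosstalkEdge(sa, sb, r_obs, p, "profile_similarity"))
    return edges


def export_network(edges, tsv_path, graphml_path=None):
    """Write an edge-list TSV and (optionally) a GraphML exchange file.

    Edge width is ``-log10(p)`` (capped at 320).  Duplicate undirected edges
    are deduplicated, logged.
    """
    unique = {}
    for e in edges:
        key = (e.set_a, e.set_b, e.mode)
        if key in unique:
            logger.info("export_network: dropped duplicate edge %s", key)
            continue
        unique[key] = e
    rows = [
        {
            "set_a": e.set_a,
            "set_b": e.set_b,
            "statistic": e.statistic,
            "p_value": e.p_value,
            "mode": e.mode,
            "width": min(-math.log10(e.p_value) if e.p_value > 0 else 320.0, 320.0),
        }
        for e in unique.values()
    ]
    pd.DataFrame(rows, columns=["set_a", "set_b", "statistic", "p_value", "mode", "width"]).to_csv(
        tsv_path, sep="\t", index=False, float_format="%.17g"
    )
    if graphml_path is not None:
        g = nx.Graph()
        for row in rows:
            g.add_edge(
                row["set_a"], row["set_b"],
                statistic=row["statistic"], p_value=row["p_value"],
                mode=row["mode"], width=row["width"],
            )
        nx.write_graphml(g, graphml_path)
    return list(unique.values())


def read_network_tsv(path):
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.empty:
        return []
    return [
        CrosstalkEdge(r.set_a, r.set_b, float(r.statistic), float(r.p_value), r.mode)
        for r in df.itertuples()
    ]
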