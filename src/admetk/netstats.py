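"""Correlation networks, Holm adjustment and over-representation analysis.

Two network flavours are used in the workflow:

* a Pearson co-response network over putative xenobiotic-related features
  on PQN-normalised data — edges where Holm-adjusted p < 0.05 and R >= 0.75;
* a Spearman dose-response network linking annotated compounds (e.g. lipids)
  to the parent xenobiotic — edges where raw p < 0.05 and |rho| >= 0.9,
  restricted to nodes with an edge to the parent.

Enrichment of compound classes among parent-correlated compounds is tested
with a one-sided Fisher exact test (hypergeometric upper tail) against the
full annotated list as the reference universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


def pairwise_correlation(
    data: pd.DataFrame, method: str = "pearson", min_obs: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs correlation of rows (compounds) across columns (samples).

    Missing values are handled pairwise-complete; pairs with fewer than
    ``min_obs`` shared observations, or with a constant vector, are recorded
    as NaN and excluded from testing.  Returns (coefficients, raw p-values),
    both symmetric with unit/NaN diagonals.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be pearson or spearman, got {method!r}")
    ids = list(data.index)
    x = data.to_numpy(dtype=float)
    n = len(ids)
    coef = np.full((n, n), np.nan)
    pval = np.full((n, n), np.nan)
    np.fill_diagonal(coef, 1.0)

    if not np.isnan(x).any() and x.shape[1] >= min_obs:
        # complete data: vectorised whole-matrix computation
        nobs = x.shape[1]
        if method == "spearman":
            from scipy.stats import rankdata
            xr = rankdata(x, axis=1)
        else:
            xr = x
        sd = xr.std(axis=1)
        ok = sd > 0
        if ok.sum() >= 2:
            r = np.corrcoef(xr[ok])
            np.clip(r, -1.0, 1.0, out=r)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = r * np.sqrt((nobs - 2) / (1 - r * r))
            p = 2 * stats.t.sf(np.abs(t), df=nobs - 2)
            p[np.isinf(t)] = 0.0
            idx = np.flatnonzero(ok)
            coef[np.ix_(idx, idx)] = r
            pval[np.ix_(idx, idx)] = p
        np.fill_diagonal(coef, 1.0)
        np.fill_diagonal(pval, np.nan)
        return (pd.DataFrame(coef, index=ids, columns=ids),
                pd.DataFrame(pval, index=ids, columns=ids))

    for i in range(n):
        for j in range(i + 1, n):
            mask = ~np.isnan(x[i]) & ~np.isnan(x[j])
            if mask.sum() < min_obs:
                continue
            a, b = x[i, mask], x[j, mask]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue  # constant vector: undefined
            if method == "pearson":
                r, p = stats.pearsonr(a, b)
            else:
                r, p = stats.spearmanr(a, b)
            coef[i, j] = coef[j, i] = r
            pval[i, j] = pval[j, i] = p
    return (pd.DataFrame(coef, index=ids, columns=ids),
            pd.DataFrame(pval, index=ids, columns=ids))


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (order of input preserved).

    NaNs are passed through and do not count towards the family size.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m:
        order = np.argsort(pv, kind="stable")
        adj = pv[order] * (m - np.arange(m))
        adj = np.minimum(np.maximum.accumulate(adj), 1.0)
        res = np.empty(m)
        res[order] = adj
        out[mask] = res
    return out


@dataclass
class CorrelationNetwork:
    """Thresholded correlation graph with per-edge statistics."""

    graph: nx.Graph
    method: str
    coef_min: float
    alpha: float
    adjusted: bool
    node_roles: dict[str, str] = field(default_factory=dict)

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, **d}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "coef", "p_raw", "p_adj"])

    def nodes_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "node": list(self.graph.nodes),
            "degree": [self.graph.degree(n) for n in self.graph.nodes],
            "role": [self.node_roles.get(n, "") for n in self.graph.nodes],
        })

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def build_network(
    coefficients: pd.DataFrame,
    pvalues: pd.DataFrame,
    coef_min: float = 0.75,
    alpha: float = 0.05,
    method: str = "pearson",
    adjust: bool = True,
    restrict_to_neighbors_of: str | None = None,
    node_roles: dict[str, str] | None = None,
) -> CorrelationNetwork:
    """Build a thresholded correlation network.

    Pearson co-response mode: Holm-adjust p over all tested pairs and keep
    edges with adjusted p < alpha and |coef| >= coef_min.  Spearman
    dose-response mode (``adjust=False``): raw p < alpha and |coef| >=
    coef_min (typically 0.9).  With ``restrict_to_neighbors_of`` set (the
    parent compound), the network keeps only the parent and nodes sharing an
    edge with it, mirroring "all nodes displayed are significantly
    correlated to the parent".
    """
    ids = list(coefficients.index)
    c = coefficients.to_numpy()
    p = pvalues.to_numpy()
    iu = np.triu_indices(len(ids), k=1)
    p_flat = p[iu]
    p_adj_flat = holm_adjust(p_flat) if adjust else p_flat.copy()

    g = nx.Graph()
    g.add_nodes_from(ids)
    for (i, j), praw, padj in zip(zip(*iu), p_flat, p_adj_flat):
        r = c[i, j]
        if np.isnan(r) or np.isnan(padj):
            continue
        if abs(r) >= coef_min and padj < alpha:
            g.add_edge(ids[i], ids[j], coef=float(r), p_raw=float(praw),
                       p_adj=float(padj))

    if restrict_to_neighbors_of is not None:
        anchor = restrict_to_neighbors_of
        if anchor not in g:
            raise ValueError(f"anchor node {anchor!r} not in network")
        keep = {anchor} | set(g.neighbors(anchor))
        g = g.subgraph(keep).copy()

    return CorrelationNetwork(
        graph=g, method=method, coef_min=coef_min, alpha=alpha,
        adjusted=adjust, node_roles=node_roles or {},
    )


def over_representation(
    universe: dict[str, str], selected, alpha: float = 0.1
) -> pd.DataFrame:
    """One-sided Fisher exact over-representation of classes in a selection.

    ``universe`` maps item -> class label (the full annotated list);
    ``selected`` is the subset of interest (e.g. compounds correlated with
    the parent).  Per class, p = P(X >= k) under the hypergeometric
    distribution with K class members in a universe of N and n selected.
    """
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected)
    stray = selected - set(universe)
    if stray:
        raise ValueError(f"selected items not in universe: {sorted(stray)}")
    N = len(universe)
    n = len(selected)
    rows = []
    for cls in sorted(set(universe.values())):
        members = {it for it, c in universe.items() if c == cls}
        K = len(members)
        k = len(members & selected)
        # upper tail P(X >= k) = survival function at k-1
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({
            "class": cls, "in_universe": K, "in_selected": k,
            "p_value": p, "enriched": p < alpha,
        })
    return pd.DataFrame(rows)
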