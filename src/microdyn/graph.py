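"""Proportionality-based co-occurrence graphs and cluster analysis.

Association between taxa is measured on CLR-transformed trajectories by
the proportionality statistic rho(x, y) = 1 - Var(x - y) / (Var(x) +
Var(y)), which is 1 for perfectly proportional series, -1 for perfectly
anti-proportional mean-free series, and near 0 for independent ones.
Taking |rho| and zeroing entries at or below a threshold yields a
*pseudosimilarity* matrix whose nonzero off-diagonal entries become
graph edges; both co-occurring and anti-co-occurring taxa are thereby
placed close together.

The graph decomposes into regions: the k largest connected components,
a "cloud" of isolated nodes and tiny components (taxa with no strong
proportionality ties), and the rest.  The region definition here is
purely graph-theoretic — independent of any stochastic layout — so
region assignments are reproducible.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

from .ordination import OrdinationResult
from .table import AbundanceSeriesTable

__all__ = [
    "proportionality_matrix",
    "pseudosimilarity_graph",
    "assign_regions",
    "region_loading_curve",
    "region_abundance_series",
    "hierarchical_partition",
    "CooccurrenceGraph",
]


def proportionality_matrix(clr_df: pd.DataFrame) -> pd.DataFrame:
    """All-vs-all proportionality rho on CLR columns.

    rho(x, y) = 1 - Var(x - y) / (Var(x) + Var(y)), population
    variances.  Symmetric, unit diagonal, values in [-1, 1]; a pair of
    zero-variance columns yields NaN.
    """
    x = np.asarray(clr_df, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 days")
    centered = x - x.mean(axis=0)
    var = centered.var(axis=0)
    n = x.shape[1]
    cov = centered.T @ centered / x.shape[0]
    denom = var[:, None] + var[None, :]
    var_diff = var[:, None] + var[None, :] - 2 * cov
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = 1.0 - var_diff / denom
    rho[denom == 0] = np.nan
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0)
    cols = list(clr_df.columns)
    return pd.DataFrame(rho, index=cols, columns=cols)


@dataclasses.dataclass
class CooccurrenceGraph:
    graph: nx.Graph
    rho_threshold: float
    components: list  # node sets sorted by decreasing size
    n_nan_pairs: int

    @property
    def nodes(self):
        return list(self.graph.nodes)


def pseudosimilarity_graph(rho: pd.DataFrame, rho_threshold: float) -> CooccurrenceGraph:
    """Build the co-occurrence graph from a proportionality matrix.

    Similarity is |rho| with entries <= threshold zeroed (strict
    inequality keeps an edge); NaN entries count as no edge.  Connected
    components are computed and ranked by size.
    """
    if not (0.0 <= rho_threshold <= 1.0):
        raise ValueError("rho_threshold must lie in [0, 1]")
    sim = np.abs(np.asarray(rho, dtype=float))
    nan_mask = ~np.isfinite(sim)
    n_nan = int(np.triu(nan_mask, 1).sum())
    sim[nan_mask] = 0.0
    g = nx.Graph()
    ids = list(rho.index)
    g.add_nodes_from(ids)
    rows, cols = np.where(np.triu(sim, 1) > rho_threshold)
    g.add_edges_from(
        (ids[i], ids[j], {"weight": float(sim[i, j])}) for i, j in zip(rows, cols)
    )
    components = sorted(
        (set(c) for c in nx.connected_components(g) if len(c) > 1),
        key=lambda c: (-len(c), sorted(c)),
    )
    return CooccurrenceGraph(g, rho_threshold, components, n_nan)


def assign_regions(
    g: CooccurrenceGraph, k_top: int = 3, min_component_size: int = 3
) -> dict[str, str]:
    """Assign every node to cloud / component_k / rest.

    Cloud collects isolated nodes and components smaller than
    ``min_component_size``; the ``k_top`` largest components get their
    own regions; everything else is "rest".
    """
    region: dict[str, str] = {}
    big = [c for c in g.components if len(c) >= min_component_size]
    for rank, comp in enumerate(big, start=1):
        name = f"component_{rank}" if rank <= k_top else "rest"
        for node in comp:
            region[node] = name
    for node in g.nodes:
        region.setdefault(node, "cloud")
    return region


def region_loading_curve(
    rho: pd.DataFrame,
    ordination: OrdinationResult,
    thresholds,
    k_top: int = 3,
    min_component_size: int = 3,
) -> pd.DataFrame:
    """Mean PC1+PC2 loading per region as the edge threshold varies.

    For each threshold the graph is rebuilt, regions reassigned, and
    |pc1| + |pc2| averaged within each region; empty regions are NaN.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    loadings = ordination.feature_loadings
    if loadings is None:
        raise ValueError("ordination carries no feature loadings")
    combined = loadings["pc1"].abs() + loadings["pc2"].abs()
    rows = []
    for thr in thresholds:
        g = pseudosimilarity_graph(rho, thr)
        regions = assign_regions(g, k_top=k_top, min_component_size=min_component_size)
        by_region: dict[str, list] = {}
        for node, reg in regions.items():
            if node in combined.index:
                by_region.setdefault(reg, []).append(combined[node])
        row = {"rho_threshold": thr}
        for reg in ["cloud", "rest"] + [f"component_{k}" for k in range(1, k_top + 1)]:
            vals = by_region.get(reg)
            row[reg] = float(np.mean(vals)) if vals else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("rho_threshold")


def region_abundance_series(
    table: AbundanceSeriesTable,
    regions: dict[str, str],
    labels: dict[str, str],
    exclude_rare_only_components: bool = False,
) -> pd.DataFrame:
    """Per-day summed counts for every (region, regime) cell.

    Optionally drops component regions whose members are all labeled
    rare.  Columns are a MultiIndex (region, regime).
    """
    region_names = sorted(set(regions.values()))
    if exclude_rare_only_components:
        drop = {
            reg
            for reg in region_names
            if reg.startswith("component_")
            and all(labels.get(a) == "rare" for a, r in regions.items() if r == reg)
        }
        region_names = [r for r in region_names if r not in drop]
    regime_names = sorted(set(labels.values()))
    cols = pd.MultiIndex.from_product(
        [region_names, regime_names], names=["region", "regime"]
    )
    out = pd.DataFrame(0.0, index=table.data.index, columns=cols)
    for asv in table.asv_ids:
        reg = regions.get(asv)
        lab = labels.get(asv)
        if reg in region_names and lab is not None:
            out[(reg, lab)] += table.data[asv]
    return out


def hierarchical_partition(similarity: pd.DataFrame, cut_height: float = 2.0) -> pd.Series:
    """Complete-linkage clustering of 1 - similarity distances.

    The linkage tree is cut at ``cut_height``; pass a signed
    proportionality matrix (distances up to 2) or a pseudosimilarity
    matrix (distances up to 1) as appropriate.
    """
    if cut_height < 0:
        raise ValueError("cut height must be non-negative")
    sim = np.asarray(similarity, dtype=float)
    if sim.shape[0] != sim.shape[1] or not np.allclose(sim, sim.T, equal_nan=True):
        raise ValueError("similarity matrix must be square and symmetric")
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    z = linkage(condensed, method="complete")
    flat = cut_tree(z, height=cut_height).ravel()
    index = similarity.index if isinstance(similarity, pd.DataFrame) else None
    return pd.Series(flat, index=index, name="cluster")
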