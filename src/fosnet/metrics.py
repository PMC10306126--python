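"""Graph-theoretic analysis of thresholded coactivation networks.

A functional connection is a region pair whose Pearson correlation exceeds
the threshold (strictly; default 0.75).  On the resulting binary undirected
graph we compute degree, geodesic betweenness (unnormalized: for each
unordered pair, the fraction of shortest paths through the node), the
participation coefficient P_i = 1 - sum_s (kappa_is / k_i)^2 against a module
partition, and the within-module degree z-score (population-sd convention).

Hubs follow a dual criterion: regions in both the top-k degree and top-k
betweenness lists (ties at the k-th value included); regions in the top-k
participation list are connector hubs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .connectome import CorrelationMatrix, ModulePartition
from .io import RunConfig, ValidationError


@dataclass
class ThresholdedNetwork:
    """Binary undirected graph of supra-threshold correlations."""

    graph: nx.Graph
    threshold: float

    @property
    def regions(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def threshold_graph(corr: CorrelationMatrix, cfg: RunConfig) -> ThresholdedNetwork:
    """Edge (i, j) iff r(i, j) > threshold, strictly; no self-loops."""
    g = nx.Graph()
    g.add_nodes_from(corr.regions)
    r = corr.r
    regions = corr.regions
    vals = r.to_numpy(float)
    n = len(regions)
    for i in range(n):
        for j in range(i + 1, n):
            if vals[i, j] > cfg.correlation_threshold:
                g.add_edge(regions[i], regions[j], r=float(vals[i, j]))
    return ThresholdedNetwork(graph=g, threshold=cfg.correlation_threshold)


def degree(net: ThresholdedNetwork) -> pd.Series:
    """Incident-edge count per region."""
    return pd.Series(dict(net.graph.degree()), name="degree").reindex(net.regions).astype(int)


def betweenness(net: ThresholdedNetwork) -> pd.Series:
    """Shortest-path betweenness, summed over unordered pairs, unnormalized.

    Disconnected pairs contribute nothing; ranks (all that hub calls use)
    are unaffected by the absent pair normalization.
    """
    b = nx.betweenness_centrality(net.graph, normalized=False)
    return pd.Series(b, name="betweenness").reindex(net.regions).astype(float)


def participation(net: ThresholdedNetwork, part: ModulePartition) -> pd.Series:
    """Guimera-Amaral participation coefficient per region.

    P_i = 1 - sum_s (kappa_is / k_i)^2 over modules s, where kappa_is counts
    i's edges into module s.  Isolated regions get 0.
    """
    module = part.module_of_region
    missing = [v for v in net.regions if v not in module]
    if missing:
        raise ValidationError(f"region(s) missing from module partition: {missing}")
    out = {}
    for v in net.regions:
        k = net.graph.degree(v)
        if k == 0:
            out[v] = 0.0
            continue
        per_module: dict[int, int] = {}
        for u in net.graph.neighbors(v):
            per_module[module[u]] = per_module.get(module[u], 0) + 1
        out[v] = 1.0 - sum((kappa / k) ** 2 for kappa in per_module.values())
    return pd.Series(out, name="participation").reindex(net.regions)


def within_module_z(net: ThresholdedNetwork, part: ModulePartition) -> pd.Series:
    """Within-module degree z-score.

    kappa_i = edges from i to nodes of its own module; z_i standardizes
    kappa_i against the mean and population standard deviation of its module
    (z = 0 when the module's within-degrees are constant, including
    singleton modules and isolated regions).
    """
    module = part.module_of_region
    missing = [v for v in net.regions if v not in module]
    if missing:
        raise ValidationError(f"region(s) missing from module partition: {missing}")
    kappa = {
        v: sum(1 for u in net.graph.neighbors(v) if module[u] == module[v]) for v in net.regions
    }
    out = {}
    by_module: dict[int, list[str]] = {}
    for v in net.regions:
        by_module.setdefault(module[v], []).append(v)
    for members in by_module.values():
        ks = np.array([kappa[v] for v in members], dtype=float)
        sd = ks.std(ddof=0)
        mean = ks.mean()
        for v in members:
            out[v] = 0.0 if sd == 0 else (kappa[v] - mean) / sd
    return pd.Series(out, name="within_module_z").reindex(net.regions)


def _top_k_with_ties(values: pd.Series, k: int) -> set[str]:
    """Indices of the k largest values; anything tied with the k-th kept."""
    if len(values) <= k:
        return set(values.index)
    ranked = values.sort_values(ascending=False)
    cutoff = ranked.iloc[k - 1]
    return set(ranked.index[ranked >= cutoff])


def centrality_table(net: ThresholdedNetwork, part: ModulePartition, cfg: RunConfig) -> pd.DataFrame:
    """Per-region centralities with hub flags.

    Columns: module, degree, betweenness, participation, within_module_z,
    is_hub_deg_btw (top-k degree AND top-k betweenness), is_connector_hub
    (top-k participation).
    """
    deg = degree(net)
    btw = betweenness(net)
    par = participation(net, part)
    z = within_module_z(net, part)
    hubs_a = _top_k_with_ties(deg, cfg.hub_top_k) & _top_k_with_ties(btw, cfg.hub_top_k)
    hubs_b = _top_k_with_ties(par, cfg.hub_top_k)
    table = pd.DataFrame(
        {
            "module": pd.Series(part.module_of_region).reindex(net.regions),
            "degree": deg,
            "betweenness": btw,
            "participation": par,
            "within_module_z": z,
        }
    )
    table["is_hub_deg_btw"] = table.index.isin(hubs_a)
    table["is_connector_hub"] = table.index.isin(hubs_b)
    table.index.name = "region_id"
    return table


def identify_hubs(cent: pd.DataFrame, cfg: RunConfig) -> dict[str, list[str]]:
    """Hub sets from a centrality table: dual degree/betweenness hubs and
    connector (participation) hubs, each top-k with ties."""
    hubs_a = _top_k_with_ties(cent["degree"], cfg.hub_top_k) & _top_k_with_ties(
        cent["betweenness"], cfg.hub_top_k
    )
    hubs_b = _top_k_with_ties(cent["participation"], cfg.hub_top_k)
    return {
        "degree_betweenness_hubs": sorted(hubs_a),
        "connector_hubs": sorted(hubs_b),
    }


@dataclass
class MannWhitneyResult:
    u: float
    p: float
    method: str


def compare_centrality(
    a, b, *, exact_limit: int = 20
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test between two centrality samples.

    U is the rank-sum statistic for sample ``a`` with midrank tie handling.
    For samples of at most ``exact_limit`` observations each the p-value is
    computed by exhaustive enumeration of rank assignments (valid under
    ties; identical samples give p = 1); larger samples use the normal
    approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    u_obs = _u_statistic(a, b)
    mu = n1 * n2 / 2.0
    if max(n1, n2) <= exact_limit and math.comb(n1 + n2, n1) <= 200_000:
        pooled = np.concatenate([a, b])
        total = math.comb(n1 + n2, n1)
        dev = abs(u_obs - mu)
        hits = sum(
            1
            for idx in combinations(range(n1 + n2), n1)
            if abs(_u_statistic(pooled[list(idx)], np.delete(pooled, list(idx))) - mu)
            >= dev - 1e-12
        )
        return MannWhitneyResult(u=u_obs, p=hits / total, method="exact")
    # normal approximation with tie correction
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return MannWhitneyResult(u=u_obs, p=1.0, method="normal")
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)  # continuity correction
    p = min(1.0, 2.0 * stats.norm.sf(max(z, 0.0)))
    return MannWhitneyResult(u=u_obs, p=p, method="normal")


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: #(a_i > b_j) + 0.5 #(a_i = b_j)."""
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())
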