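"""Co-occurrence network construction and topology.

Taxa surviving an abundance/prevalence filter are correlated pairwise by
Spearman's rank coefficient on relative abundances; edges keep pairs with
|rho| above a threshold and a Benjamini-Hochberg q below a cap.  Topology
is computed with networkx on the resulting undirected graph, at node level
(degree, closeness, betweenness, eccentricity) and network level (average
degree, density, clustering, path length, modularity).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import CountTable, filter_taxa, to_relative

__all__ = ["NetworkStats", "build_network", "network_stats", "write_edge_list"]


def _spearman_matrix(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman rho and two-sided t-approximation p-values.

    Constant columns yield rho = 0, p = 1 (no monotone association is
    measurable).
    """
    n = x.shape[0]
    ranks = np.apply_along_axis(stats.rankdata, 0, x)
    sd = ranks.std(axis=0)
    constant = sd == 0
    z = ranks - ranks.mean(axis=0)
    z[:, ~constant] /= sd[~constant] * np.sqrt(n)
    rho = z.T @ z
    rho = np.clip(rho, -1.0, 1.0)
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(p), 0.0, p)  # |rho| == 1 -> p = 0
    p[constant, :] = 1.0
    p[:, constant] = 1.0
    return rho, p


def _spearman_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided permutation p for one pair (tiny n only)."""
    ra, rb = stats.rankdata(a), stats.rankdata(b)
    obs = abs(stats.spearmanr(a, b).statistic)
    count = 0
    total = 0
    for perm in itertools.permutations(range(len(a))):
        r = abs(stats.spearmanr(ra, rb[list(perm)]).statistic)
        count += r >= obs - 1e-12
        total += 1
    return count / total


def build_network(
    ct: CountTable,
    min_mean_relabund: float = 1e-4,
    min_prev: float = 0.3,
    rho_min: float = 0.6,
    q_max: float = 0.05,
    exact_p: bool = False,
) -> nx.Graph:
    """Filtered Spearman co-occurrence network.

    Filters taxa (mean relative abundance >= ``min_mean_relabund`` and
    prevalence >= ``min_prev``), correlates all surviving pairs, corrects p
    across all pairs by Benjamini-Hochberg, and keeps edges with
    ``|rho| > rho_min`` and ``q < q_max``.  Edge attributes: rho, p, q, sign.
    With ``exact_p=True`` and fewer than 10 samples, p-values come from full
    permutation enumeration instead of the t approximation.
    """
    if ct.n_samples < 5:
        raise ValueError("need at least 5 samples to build a network")
    kept = filter_taxa(ct, min_mean_relabund, min_prev)
    g = nx.Graph()
    g.add_nodes_from(kept.taxon_ids)
    if kept.n_taxa < 2:
        warnings.warn("fewer than 2 taxa survive filtering; empty network")
        return g

    rel = to_relative_safe(kept)
    x = rel.to_numpy(dtype=float)
    rho, p = _spearman_matrix(x)
    iu = np.triu_indices(kept.n_taxa, k=1)
    pvals = p[iu]
    if exact_p and ct.n_samples < 10:
        pvals = np.array(
            [_spearman_exact_p(x[:, i], x[:, j]) for i, j in zip(*iu)]
        )
    qvals = multipletests(pvals, method="fdr_bh")[1]

    ids = kept.taxon_ids
    for (i, j), pv, qv in zip(zip(*iu), pvals, qvals):
        r = rho[i, j]
        if abs(r) > rho_min and qv < q_max:
            g.add_edge(
                ids[i],
                ids[j],
                rho=float(r),
                p=float(pv),
                q=float(qv),
                sign="positive" if r > 0 else "negative",
            )
    return g


def to_relative_safe(kept: CountTable) -> pd.DataFrame:
    # after taxon filtering a sample may have zero reads among survivors;
    # keep it as all-zero rather than erroring
    totals = kept.data.sum(axis=1)
    return kept.data.div(totals.replace(0, 1), axis=0)


@dataclass(frozen=True)
class NetworkStats:
    n_nodes: int
    n_edges: int
    positive_edges: int
    negative_edges: int
    avg_degree: float
    density: float
    avg_clustering: float
    avg_path_length: float
    modularity: float
    node_stats: pd.DataFrame  # degree, closeness, betweenness, eccentricity


def network_stats(g: nx.Graph, closeness: str = "harmonic") -> NetworkStats:
    """Node- and network-level topology.

    Disconnected graphs are handled per component: eccentricity within each
    node's component, average path length over reachable pairs, and (by
    default) harmonic closeness which is well defined under disconnection.
    Modularity uses deterministic greedy agglomeration on the unsigned,
    unweighted graph.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    n, e = g.number_of_nodes(), g.number_of_edges()
    signs = [d.get("sign", "positive") for _, _, d in g.edges(data=True)]
    pos = sum(s == "positive" for s in signs)

    degree = dict(g.degree())
    if closeness == "harmonic":
        close = {k: v / (n - 1) if n > 1 else 0.0 for k, v in nx.harmonic_centrality(g).items()}
    elif closeness == "classic":
        close = nx.closeness_centrality(g)
    else:
        raise ValueError("closeness must be 'harmonic' or 'classic'")
    between = nx.betweenness_centrality(g, normalized=False)

    ecc: dict = {}
    path_sum = 0
    path_pairs = 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if len(comp) == 1:
            ecc[next(iter(comp))] = 0
            continue
        ecc.update(nx.eccentricity(sub))
        for src, dists in nx.shortest_path_length(sub):
            path_sum += sum(dists.values())
            path_pairs += len(dists) - 1
    avg_path = path_sum / path_pairs if path_pairs else 0.0

    if e > 0:
        comms = nx.community.greedy_modularity_communities(g)
        modularity = float(nx.community.modularity(g, comms))
    else:
        modularity = 0.0

    nodes = sorted(g.nodes())
    node_stats = pd.DataFrame(
        {
            "degree": [degree[v] for v in nodes],
            "closeness": [close[v] for v in nodes],
            "betweenness": [between[v] for v in nodes],
            "eccentricity": [ecc[v] for v in nodes],
        },
        index=nodes,
    )
    return NetworkStats(
        n_nodes=n,
        n_edges=e,
        positive_edges=pos,
        negative_edges=e - pos,
        avg_degree=2.0 * e / n,
        density=2.0 * e / (n * (n - 1)) if n > 1 else 0.0,
        avg_clustering=float(nx.average_clustering(g)) if n > 0 else 0.0,
        avg_path_length=float(avg_path),
        modularity=modularity,
        node_stats=node_stats,
    )


def write_edge_list(g: nx.Graph, path) -> None:
    rows = [
        {"source": u, "target": v, **d}
        for u, v, d in sorted(g.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "rho", "p", "q", "sign"]).to_csv(
        path, sep="\t", index=False
    )
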