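"""Enterotype-stratified partial-correlation co-occurrence networks."""

from __future__ import annotations

import dataclasses
import logging

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats

from rumenet.phenotype import bh_adjust
from rumenet.tables import AbundanceTable

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class CoNetwork:
    label: str
    nodes: list[str]                 # genera with >= 1 retained edge
    edges: pd.DataFrame              # a, b (a < b), r, p, q
    candidate_genera: list[str]      # genera entering the test

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for _, row in self.edges.iterrows():
            g.add_edge(row["a"], row["b"], r=row["r"], q=row["q"])
        return g


@dataclasses.dataclass
class NetworkTopology:
    n_vertices: int
    n_edges: int
    clustering_coefficient: float
    average_distance: float
    average_betweenness: float
    degree: pd.Series


def select_network_genera(
    tab: AbundanceTable,
    min_prevalence: float = 0.50,
    min_mean_rel_abund: float = 0.001,
) -> list[str]:
    """Genera present in >= ``min_prevalence`` of samples AND with mean
    relative abundance strictly > ``min_mean_rel_abund``."""
    if tab.n_samples == 0:
        raise ValueError("empty table")
    prev = (tab.counts > 0).mean(axis=0)
    mean_rel = tab.rel_abundance.mean(axis=0)
    keep = (prev >= min_prevalence) & (mean_rel > min_mean_rel_abund)
    genera = [g for g, k in zip(tab.genus_ids, keep) if k]
    if not genera:
        raise ValueError("no genera pass the network filters")
    return genera


def spearman_partial_matrix(
    tab: AbundanceTable, genera: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman partial correlations controlling for all other genera.

    Relative abundances are taken from the FULL table and then restricted to
    ``genera`` (no renormalization over the subset, which would reintroduce
    closure artifacts). Columns are rank-transformed; the partial correlation
    matrix comes from the (pseudo-)inverse of the rank correlation matrix.
    p-values use the t approximation with df = n - g, g the number of
    retained genera.
    """
    rel = tab.rel_abundance
    if genera is not None:
        cols = [tab.genus_ids.index(gn) for gn in genera]
        rel = rel[:, cols]
        ids = list(genera)
    else:
        ids = list(tab.genus_ids)
    n, g = rel.shape
    ranks = np.apply_along_axis(scipy.stats.rankdata, 0, rel)
    corr = np.corrcoef(ranks, rowvar=False)
    try:
        prec = np.linalg.inv(corr)
        if not np.all(np.isfinite(prec)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        logger.warning("singular rank-correlation matrix; using pseudo-inverse")
        prec = np.linalg.pinv(corr)
    d = np.sqrt(np.abs(np.diag(prec)))
    pr = -prec / np.outer(d, d)
    np.fill_diagonal(pr, 1.0)
    pr = np.clip((pr + pr.T) / 2, -1.0, 1.0)
    df_resid = n - g
    if df_resid <= 0:
        logger.warning("nonpositive residual df (n=%d, g=%d); p-values set to 1", n, g)
        pmat = np.ones_like(pr)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = pr * np.sqrt(df_resid / (1 - pr**2))
        pmat = 2 * scipy.stats.t.sf(np.abs(t), df_resid)
        pmat = np.where(np.abs(pr) >= 1.0, 0.0, pmat)
    np.fill_diagonal(pmat, np.nan)
    return (pd.DataFrame(pr, index=ids, columns=ids),
            pd.DataFrame(pmat, index=ids, columns=ids))


def build_network(
    r: pd.DataFrame, p: pd.DataFrame, fdr: float = 0.05, label: str = ""
) -> CoNetwork:
    """Keep edges whose BH-adjusted p over the upper triangle is <= fdr."""
    ids = list(r.index)
    iu, ju = np.triu_indices(len(ids), 1)
    pv = p.to_numpy()[iu, ju]
    rv = r.to_numpy()[iu, ju]
    q = bh_adjust(pv)
    keep = q <= fdr
    edges = pd.DataFrame({
        "a": [min(ids[i], ids[j]) for i, j in zip(iu[keep], ju[keep])],
        "b": [max(ids[i], ids[j]) for i, j in zip(iu[keep], ju[keep])],
        "r": rv[keep], "p": pv[keep], "q": q[keep],
    }).sort_values(["a", "b"], ignore_index=True)
    nodes = sorted(set(edges["a"]) | set(edges["b"]))
    return CoNetwork(label, nodes, edges, ids)


def network_from_table(
    tab: AbundanceTable,
    label: str = "",
    min_prevalence: float = 0.50,
    min_mean_rel_abund: float = 0.001,
    fdr: float = 0.05,
) -> CoNetwork:
    """Filter genera, compute partial correlations, and threshold at FDR."""
    genera = select_network_genera(tab, min_prevalence, min_mean_rel_abund)
    r, p = spearman_partial_matrix(tab, genera)
    return build_network(r, p, fdr=fdr, label=label)


def network_topology(net: CoNetwork) -> NetworkTopology:
    """Global transitivity, mean shortest path on the largest component,
    mean normalized betweenness, and per-node degree."""
    g = net.graph()
    if g.number_of_edges() == 0:
        raise ValueError("network has no edges; topology undefined")
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    giant = g.subgraph(comps[0])
    avg_dist = nx.average_shortest_path_length(giant) if giant.number_of_nodes() > 1 else np.nan
    btw = nx.betweenness_centrality(g, normalized=True)
    deg = pd.Series(dict(g.degree()), dtype=int).sort_index()
    return NetworkTopology(
        n_vertices=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        clustering_coefficient=float(nx.transitivity(g)),
        average_distance=float(avg_dist),
        average_betweenness=float(np.mean(list(btw.values()))),
        degree=deg,
    )


def classify_generalist_edges(
    net_e1: CoNetwork,
    net_e2: CoNetwork,
    strength_delta: float = 0.2,
    strength_on_abs: bool = False,
) -> pd.DataFrame:
    """Specialist/generalist split plus direction/strength/stable taxonomy.

    Pairs significant in exactly one network are specialists; pairs in both
    are generalists, classified (mutually exclusively, direction first) as
      direction_change  sign(r_E1) * sign(r_E2) < 0,
      strength_change   same sign and |r_E1 - r_E2| > strength_delta
                        (or ||r_E1|-|r_E2|| when ``strength_on_abs``),
      stable            otherwise.
    """
    def edge_map(net: CoNetwork) -> dict[tuple[str, str], float]:
        return {(row["a"], row["b"]): row["r"] for _, row in net.edges.iterrows()}

    m1, m2 = edge_map(net_e1), edge_map(net_e2)
    rows = []
    for pair in sorted(set(m1) | set(m2)):
        r1, r2 = m1.get(pair), m2.get(pair)
        if r1 is not None and r2 is not None:
            status = "generalist"
            if np.sign(r1) * np.sign(r2) < 0:
                gclass = "direction_change"
            else:
                delta = abs(abs(r1) - abs(r2)) if strength_on_abs else abs(r1 - r2)
                gclass = "strength_change" if delta > strength_delta else "stable"
        else:
            status = "specialist_E1" if r1 is not None else "specialist_E2"
            gclass = None
        rows.append({"a": pair[0], "b": pair[1], "r_E1": r1, "r_E2": r2,
                     "status": status, "generalist_class": gclass})
    return pd.DataFrame(rows)


def node_sign_profile_and_key_taxa(
    net: CoNetwork, top_n: int = 10
) -> tuple[pd.DataFrame, list[str]]:
    """Per-node positive/negative incident-edge counts and top-degree taxa.

    The log10(neg/pos) ratio is NaN whenever either count is zero. Key taxa
    are the ``top_n`` nodes by degree, ties broken alphabetically.
    """
    pos = dict.fromkeys(net.nodes, 0)
    neg = dict.fromkeys(net.nodes, 0)
    for _, row in net.edges.iterrows():
        bucket = pos if row["r"] > 0 else neg
        bucket[row["a"]] += 1
        bucket[row["b"]] += 1
    df = pd.DataFrame({
        "node": net.nodes,
        "pos_edges": [pos[v] for v in net.nodes],
        "neg_edges": [neg[v] for v in net.nodes],
    })
    df["degree"] = df["pos_edges"] + df["neg_edges"]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log10(df["neg_edges"] / df["pos_edges"])
    df["log10_neg_pos"] = np.where(
        (df["neg_edges"] > 0) & (df["pos_edges"] > 0), ratio, np.nan)
    key = list(df.sort_values(["degree", "node"], ascending=[False, True])
               .head(top_n)["node"])
    return df, key
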