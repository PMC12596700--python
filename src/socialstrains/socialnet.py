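"""Strain-sharing networks, centralities, and nonparametric group statistics.

The network has individuals as nodes and an undirected edge wherever two
individuals share at least one strain, weighted by the number of shared
strains. Degree is reported unweighted (the number of connections a node
holds), eigenvector centrality comes from the principal eigenvector of the
weighted adjacency (max-normalized; nodes outside the dominant component get
~0), and betweenness is shortest-path betweenness on the unweighted graph.

Group comparisons follow the usual nonparametric battery: Wilcoxon rank-sum
with effect size r = |Z|/sqrt(N) for two groups, Kruskal-Wallis with post-hoc
Dunn tests (tie-corrected z, Benjamini-Hochberg adjusted) for more, and
Spearman correlations.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "build_network",
    "centralities",
    "compare_groups",
    "dunn_posthoc",
    "correlate",
]


def build_network(rates: pd.DataFrame, roster: pd.DataFrame) -> nx.Graph:
    """Undirected weighted graph from the pairwise sharing table.

    Every roster individual becomes a node (with group/role/sex attributes);
    pairs with ``n_shared_strains`` > 0 get an edge of that weight.
    """
    g = nx.Graph()
    known = set(roster["individual_id"])
    for row in roster.itertuples():
        g.add_node(
            str(row.individual_id),
            social_group=str(row.social_group),
            role=str(getattr(row, "role", "NA")),
            sex=str(getattr(row, "sex", "NA")),
        )
    for row in rates.itertuples():
        a, b = row.individual_a, row.individual_b
        if a not in known or b not in known:
            raise ValueError(f"pair ({a}, {b}) references unknown individual")
        if a == b:
            continue
        w = int(row.n_shared_strains)
        if w > 0:
            # symmetric duplicates collapse onto one undirected edge
            g.add_edge(a, b, weight=max(w, g.edges[a, b]["weight"]) if g.has_edge(a, b) else w)
    return g


def centralities(g: nx.Graph) -> pd.DataFrame:
    """Degree (unweighted), weighted degree, eigenvector and betweenness centrality."""
    if g.number_of_nodes() == 0:
        raise ValueError("network has no nodes")
    nodes = sorted(g.nodes)
    adj = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    if adj.any():
        vals, vecs = np.linalg.eigh(adj)
        vec = np.abs(vecs[:, np.argmax(vals)])
        eig = vec / vec.max()
        # numerical zeros off the dominant component
        eig[eig < 1e-12] = 0.0
    else:
        eig = np.zeros(len(nodes))
    betw = nx.betweenness_centrality(g, normalized=True, weight=None)
    return pd.DataFrame(
        {
            "individual_id": nodes,
            "degree": [g.degree(n) for n in nodes],
            "weighted_degree": [g.degree(n, weight="weight") for n in nodes],
            "eigenvector": eig,
            "betweenness": [betw[n] for n in nodes],
        }
    )


def _rank_sum_two_groups(x: np.ndarray, y: np.ndarray) -> dict:
    n1, n2 = len(x), len(y)
    n = n1 + n2
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    # z from the tie-corrected normal approximation, for the effect size r
    _, ties = np.unique(np.concatenate([x, y]), return_counts=True)
    sigma = np.sqrt(n1 * n2 / 12.0 * ((n + 1) - np.sum(ties**3 - ties) / (n * (n - 1))))
    z = (float(res.statistic) - n1 * n2 / 2.0) / sigma if sigma > 0 else 0.0
    return {
        "test": "wilcoxon-rank-sum",
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "z": z,
        "effect_size_r": abs(z) / np.sqrt(n),
    }


def compare_groups(values, labels) -> dict:
    """Omnibus nonparametric comparison of a numeric variable across groups.

    Two groups: Wilcoxon rank-sum (exact where scipy selects it) with effect
    size r = |Z|/sqrt(N). More: tie-corrected Kruskal-Wallis H with chi-square
    p plus pairwise Dunn tests under 'posthoc'.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(values) != len(labels):
        raise ValueError("values and labels differ in length")
    groups = [values[labels == lab] for lab in pd.unique(labels)]
    names = list(pd.unique(labels))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 1 for g in groups):
        raise ValueError("every group needs at least one observation")
    if len(groups) == 2:
        return _rank_sum_two_groups(groups[0], groups[1])
    if np.ptp(values) == 0:  # all observations identical: no evidence of difference
        return {"test": "kruskal-wallis", "statistic": 0.0, "p": 1.0, "posthoc": None}
    h, p = stats.kruskal(*groups)
    return {
        "test": "kruskal-wallis",
        "statistic": float(h),
        "p": float(p),
        "posthoc": dunn_posthoc(values, labels, names),
    }


def dunn_posthoc(values, labels, group_names=None) -> pd.DataFrame:
    """Pairwise Dunn z-tests on ranks with BH-adjusted two-sided p-values.

    Uses the tie-corrected pooled variance
    ``(N(N+1)/12 - sum(t^3 - t)/(12(N-1))) * (1/n_i + 1/n_j)``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if group_names is None:
        group_names = list(pd.unique(labels))
    ranks = stats.rankdata(values)
    n = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n - 1))
    rows = []
    for a, b in combinations(group_names, 2):
        ra, rb = ranks[labels == a], ranks[labels == b]
        var = (n * (n + 1) / 12.0 - tie_term) * (1.0 / len(ra) + 1.0 / len(rb))
        z = (ra.mean() - rb.mean()) / np.sqrt(var)
        rows.append({"group_a": a, "group_b": b, "z": z, "p": 2 * stats.norm.sf(abs(z))})
    out = pd.DataFrame(rows)
    out["p_adj"] = stats.false_discovery_control(out["p"], method="bh")
    return out


def correlate(x, y, method: str = "spearman") -> dict:
    """Correlation between paired vectors; Spearman (tie-aware) by default."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of equal length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"method": method, "rho": np.nan, "p": np.nan, "degenerate": True}
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
    elif method == "pearson":
        rho, p = stats.pearsonr(x, y)
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")
    return {"method": method, "rho": float(rho), "p": float(p), "degenerate": False}
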