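"""Variable-level correlation networks and patient-level self-similarity.

The correlation network has one node per cohort variable; edges connect
pairs whose pairwise-complete Pearson |r| exceeds a threshold (default
0.45). An edge is additionally flagged *significant* when it rests on more
than ``n_min`` paired observations (default 82) and its t-transform p-value
clears a multiplicity-adjusted threshold (default 1.2e-6, i.e. 0.05 over
the 291*290/2 variable pairs). The certainty index is the percentage of
variables participating in at least one significant correlation.

Patient self-similarity is the cosine similarity of z-scored feature
vectors ("dot product" similarity after normalisation); missing entries are
imputed to the column mean (0 after z-scoring).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats as sstats

from .exceptions import NetworkError
from .io import CohortTable


@dataclass
class CorrelationNetwork:
    """Weighted undirected graph over variables.

    Edge attributes: ``weight`` (Pearson r), ``n_obs``, ``p``,
    ``significant``. Node attribute ``all_missing`` flags variables with no
    data (retained at degree 0).
    """

    graph: nx.Graph
    r_threshold: float
    n_min: int
    p_threshold: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def significant_subgraph(self) -> nx.Graph:
        keep = [(u, v) for u, v, d in self.graph.edges(data=True) if d["significant"]]
        sub = nx.Graph()
        sub.add_nodes_from(self.graph.nodes(data=True))
        sub.add_edges_from((u, v, self.graph.edges[u, v]) for u, v in keep)
        return sub

    def edge_frame(self) -> pd.DataFrame:
        rows = [{"source": u, "target": v, **d}
                for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["source", "target", "weight",
                                           "n_obs", "p", "significant"])


def pairwise_pearson(frame: pd.DataFrame):
    """Pairwise-complete Pearson r, n_obs, and t-transform p per variable pair.

    Returns (r, n, p) as DataFrames indexed/columned by variable. p uses
    t = r*sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom; pairs with n < 3
    get p = NaN.
    """
    r = frame.corr(method="pearson", min_periods=2)
    present = frame.notna().astype(float)
    n = pd.DataFrame(present.T.to_numpy() @ present.to_numpy(),
                     index=frame.columns, columns=frame.columns)
    with np.errstate(divide="ignore", invalid="ignore"):
        rv = r.to_numpy()
        nv = n.to_numpy()
        t = rv * np.sqrt((nv - 2) / np.clip(1.0 - rv ** 2, 1e-300, None))
        p = 2.0 * sstats.t.sf(np.abs(t), np.maximum(nv - 2, 1))
        p[nv < 3] = np.nan
        p[np.abs(rv) >= 1.0] = 0.0
        p[~np.isfinite(rv)] = np.nan
    return r, n, pd.DataFrame(p, index=frame.columns, columns=frame.columns)


def correlation_network(table: CohortTable | pd.DataFrame,
                        r_threshold: float = 0.45, n_min: int = 82,
                        p_threshold: float = 1.2e-6,
                        variables: list[str] | None = None) -> CorrelationNetwork:
    """Build the thresholded Pearson correlation network of cohort variables."""
    frame = table.data if isinstance(table, CohortTable) else table
    if variables is None:
        variables = (table.numeric_columns() if isinstance(table, CohortTable)
                     else [c for c in frame.columns
                           if pd.api.types.is_numeric_dtype(frame[c])])
    frame = frame[variables]
    if len(frame) < 3:
        raise NetworkError("need at least 3 patients to build a network")
    r, n, p = pairwise_pearson(frame)
    graph = nx.Graph()
    for col in variables:
        graph.add_node(col, all_missing=bool(frame[col].isna().all()))
    for i, u in enumerate(variables):
        for v in variables[i + 1:]:
            rv = r.loc[u, v]
            if not np.isfinite(rv) or abs(rv) <= r_threshold:
                continue
            n_obs = int(n.loc[u, v])
            pv = float(p.loc[u, v])
            significant = bool(n_obs > n_min and np.isfinite(pv) and pv < p_threshold)
            graph.add_edge(u, v, weight=float(rv), n_obs=n_obs, p=pv,
                           significant=significant)
    return CorrelationNetwork(graph, r_threshold, n_min, p_threshold)


@dataclass
class NetworkMetrics:
    degree: dict[str, int]
    betweenness: dict[str, float]
    path_lengths: dict[tuple[str, str], int]
    n_disconnected_pairs: int

    def path_length_distribution(self) -> dict[int, int]:
        dist: dict[int, int] = {}
        for length in self.path_lengths.values():
            dist[length] = dist.get(length, 0) + 1
        return dist

    def mean_shortest_path(self) -> float:
        vals = list(self.path_lengths.values())
        return float(np.mean(vals)) if vals else np.nan


def network_metrics(net: CorrelationNetwork,
                    significant_only: bool = False) -> NetworkMetrics:
    """Degree, normalised betweenness centrality, and shortest-path lengths.

    Computed on the unweighted graph; with ``significant_only=True`` only
    edges flagged significant are used. Disconnected pairs are counted
    separately rather than assigned infinite length.
    """
    graph = net.significant_subgraph() if significant_only else net.graph
    degree = dict(graph.degree())
    betweenness = nx.betweenness_centrality(graph, normalized=True)
    path_lengths: dict[tuple[str, str], int] = {}
    nodes = sorted(graph.nodes)
    reached = dict(nx.all_pairs_shortest_path_length(graph))
    disconnected = 0
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            if v in reached.get(u, {}):
                path_lengths[(u, v)] = int(reached[u][v])
            else:
                disconnected += 1
    return NetworkMetrics(degree, betweenness, path_lengths, disconnected)


def rewiring_scores(net_a: CorrelationNetwork,
                    net_b: CorrelationNetwork) -> dict[str, float]:
    """Per-node neighbourhood dissimilarity between two networks, in [0, 1].

    For each node, 1 minus the cosine similarity of its edge-weight vectors
    (absent edges weigh 0) in the two networks. Identical neighbourhoods
    score 0; disjoint ones score 1. Nodes isolated in both networks score 0
    (nothing rewired).
    """
    nodes_a, nodes_b = set(net_a.graph.nodes), set(net_b.graph.nodes)
    if nodes_a != nodes_b:
        raise NetworkError(
            f"node sets differ: {sorted(nodes_a ^ nodes_b)}")
    nodes = sorted(nodes_a)
    scores = {}
    for node in nodes:
        wa = np.array([net_a.graph.edges[node, o]["weight"]
                       if net_a.graph.has_edge(node, o) else 0.0 for o in nodes])
        wb = np.array([net_b.graph.edges[node, o]["weight"]
                       if net_b.graph.has_edge(node, o) else 0.0 for o in nodes])
        na, nb = np.linalg.norm(wa), np.linalg.norm(wb)
        if na == 0.0 and nb == 0.0:
            scores[node] = 0.0
        elif na == 0.0 or nb == 0.0:
            scores[node] = 1.0
        else:
            scores[node] = float(np.clip(1.0 - wa @ wb / (na * nb), 0.0, 2.0))
    return scores


def certainty_index(net: CorrelationNetwork, n_variables: int = 291) -> float:
    """Percent of variables participating in >=1 significant correlation."""
    if n_variables <= 0:
        raise NetworkError("n_variables must be positive")
    involved = {node for u, v, d in net.graph.edges(data=True)
                if d["significant"] for node in (u, v)}
    return 100.0 * len(involved) / n_variables


# ---------------------------------------------------------------------------
# patient self-similarity
# ---------------------------------------------------------------------------

@dataclass
class SimilarityMatrix:
    """Square patient-by-patient cosine similarity with group labels."""

    matrix: pd.DataFrame
    labels: pd.Series

    @property
    def n_patients(self) -> int:
        return len(self.matrix)


@dataclass
class SimilarityResult:
    similarity: SimilarityMatrix
    median_within_event: float
    median_between: float
    permutation_p: float


def _pair_medians(values: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    iu = np.triu_indices(len(labels), k=1)
    sims = values[iu]
    li, lj = labels[iu[0]], labels[iu[1]]
    within = sims[(li == 1) & (lj == 1)]
    between = sims[li != lj]
    med_w = float(np.median(within)) if len(within) else np.nan
    med_b = float(np.median(between)) if len(between) else np.nan
    return med_w, med_b


def patient_similarity(table: CohortTable | pd.DataFrame, group_col: str,
                       n_permutations: int = 1000,
                       rng: np.random.Generator | int | None = 0,
                       raw_dot_product: bool = False) -> SimilarityResult:
    """Patient-to-patient cosine similarity over z-scored features.

    Reports the median similarity among event-event pairs versus
    event-vs-nonevent pairs, with a label-permutation p-value for the
    difference of medians. ``raw_dot_product=True`` skips the row
    normalisation (not recommended; scale-dominated).
    """
    frame = table.data if isinstance(table, CohortTable) else table
    features = [c for c in (table.numeric_columns() if isinstance(table, CohortTable)
                            else frame.columns)
                if c != group_col and pd.api.types.is_numeric_dtype(frame[c])]
    labels = frame[group_col].astype(int)
    x = frame[features].to_numpy(dtype=float)
    all_missing = np.isnan(x).all(axis=1)
    if all_missing.any():
        warnings.warn(f"excluding {int(all_missing.sum())} patient(s) with "
                      "all-missing features")
        x = x[~all_missing]
        labels = labels[~all_missing]
    mu = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0)
    sd[sd == 0.0] = 1.0
    z = (x - mu) / sd
    z[np.isnan(z)] = 0.0  # column-mean imputation after z-scoring
    if raw_dot_product:
        sim = z @ z.T
    else:
        norms = np.linalg.norm(z, axis=1)
        norms[norms == 0.0] = 1.0
        sim = (z / norms[:, None]) @ (z / norms[:, None]).T
        np.fill_diagonal(sim, 1.0)
    ids = frame.index[~all_missing]
    matrix = SimilarityMatrix(
        pd.DataFrame(sim, index=ids, columns=ids), labels)

    lab = labels.to_numpy()
    med_w, med_b = _pair_medians(sim, lab)
    observed = med_w - med_b
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(lab)
        w, b = _pair_medians(sim, perm)
        if (w - b) >= observed:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return SimilarityResult(matrix, med_w, med_b, p)


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def export_graphml(net: CorrelationNetwork, path) -> None:
    nx.write_graphml(net.graph, path)


def export_edge_csv(net: CorrelationNetwork, path) -> None:
    net.edge_frame().to_csv(path, index=False)


def export_force_layout_json(net: CorrelationNetwork, path) -> None:
    """Nodes/links JSON consumable by a D3-style force layout."""
    import json
    nodes = [{"id": n, **{k: bool(v) if isinstance(v, np.bool_) else v
                          for k, v in d.items()}}
             for n, d in net.graph.nodes(data=True)]
    links = [{"source": u, "target": v, "value": d["weight"],
              "significant": bool(d["significant"])}
             for u, v, d in net.graph.edges(data=True)]
    with open(path, "w") as fh:
        json.dump({"nodes": nodes, "links": links}, fh, indent=1)
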