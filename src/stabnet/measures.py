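"""Node-level measures and the maximal spanning tree of an estimated network.

Weight conventions (documented here once, used everywhere): centrality and
spanning-tree computations run on the *absolute* partial correlations of the
supported edges; shortest-path measures use distance = 1 / |weight|;
current-flow measures use |weight| as an electrical conductance.  Signed
weights are preserved in the reported outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import DataTable
from .model import GGMResults


@dataclass
class MeasureReport:
    """Per-node values of one network measure."""

    node_labels: list[str]
    measure: str
    values: np.ndarray
    context: str = "training"

    def series(self) -> pd.Series:
        return pd.Series(self.values, index=self.node_labels, name=self.measure)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": self.node_labels,
                "measure": self.measure,
                "context": self.context,
                "value": self.values,
            }
        )


@dataclass
class SpanningTree:
    """Maximal spanning forest: edges carry the signed partial correlation."""

    edges: list[tuple[str, str, float]]
    total_weight: float  # sum of |weight| over tree edges

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["node_i", "node_j", "weight"])

    def to_graph(self) -> nx.Graph:
        G = nx.Graph()
        for u, v, w in self.edges:
            G.add_edge(u, v, weight=w, abs_weight=abs(w))
        return G


# ---------------------------------------------------------------------------
# predictability
# ---------------------------------------------------------------------------
def predictability(model: GGMResults) -> np.ndarray:
    """Per-node percentage of variance explained by its neighbors.

    On the standardized scale the GGM implies a residual variance of
    ``1 / theta_ii`` for node i, so R^2_i = 1 - 1/theta_ii; an isolated node
    has theta_ii = 1 and 0% predictability.
    """
    d = np.diag(model.theta)
    vals = 100.0 * (1.0 - 1.0 / d)
    # on unit-variance data theta_ii >= 1, so negatives are solver round-off
    return np.maximum(vals, 0.0)


def node_coefficients(model: GGMResults, i: int) -> np.ndarray:
    """Implied regression coefficients of node i on all others."""
    beta = -model.theta[i] / model.theta[i, i]
    beta[i] = 0.0
    return beta


def holdout_predictability(model: GGMResults, test: DataTable | np.ndarray) -> np.ndarray:
    """Out-of-sample R^2 (x100) of each node-wise implied regression.

    The test table must be transformed/standardized with the training
    transform.  R^2 = 1 - SSE/SST with SST about the test mean; values can be
    negative when the implied regression predicts worse than the mean.
    """
    if isinstance(test, DataTable):
        if list(test.columns) != list(model.node_labels):
            raise ValueError(
                "test columns do not match model nodes: "
                f"{list(test.columns)} vs {model.node_labels}"
            )
        X = test.values()
    else:
        X = np.asarray(test, dtype=float)
        if X.shape[1] != model.p:
            raise ValueError("test column count does not match model nodes")
    out = np.empty(model.p)
    for i in range(model.p):
        beta = node_coefficients(model, i)
        pred = X @ beta
        y = X[:, i]
        sse = float(np.sum((y - pred) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        out[i] = 100.0 * (1.0 - sse / sst) if sst > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# centralities
# ---------------------------------------------------------------------------
def degree_centrality(model: GGMResults) -> np.ndarray:
    """Fraction of the other nodes each node is connected to."""
    return model.support.sum(axis=1) / (model.p - 1)


def _abs_adjacency(model: GGMResults) -> np.ndarray:
    return np.abs(model.partial_corr) * model.support


def _components(adj: np.ndarray) -> list[list[int]]:
    G = nx.from_numpy_array(adj)
    return [sorted(c) for c in nx.connected_components(G)]


def current_flow_closeness(model: GGMResults) -> np.ndarray:
    """Effective-resistance (information) closeness, per connected component.

    For node v in a component of size m: value = (m - 1) / sum_t R_eff(v, t),
    where R_eff comes from the pseudoinverse of the component's weighted
    Laplacian with conductances |partial correlation|.  Isolated nodes get 0.
    """
    adj = _abs_adjacency(model)
    out = np.zeros(model.p)
    for comp in _components(adj):
        m = len(comp)
        if m == 1:
            continue
        A = adj[np.ix_(comp, comp)]
        L = np.diag(A.sum(axis=1)) - A
        Lp = np.linalg.pinv(L)
        d = np.diag(Lp)
        # R_eff(v, t) = Lp_vv + Lp_tt - 2 Lp_vt
        R = d[:, None] + d[None, :] - 2.0 * Lp
        out[comp] = (m - 1) / R.sum(axis=1)
    return out


def classical_centralities(model: GGMResults) -> dict[str, np.ndarray]:
    """Closeness, betweenness and current-flow betweenness per node.

    Shortest-path measures use distance 1/|weight|; closeness is component
    local (no small-component inflation correction); current-flow betweenness
    uses |weight| as conductance, computed per component with component-local
    normalization.
    """
    G = model.to_graph()
    for _u, _v, d in G.edges(data=True):
        d["dist"] = 1.0 / d["abs_weight"]
    labels = list(model.node_labels)
    pos = {lab: k for k, lab in enumerate(labels)}

    clo = np.zeros(model.p)
    for lab, val in nx.closeness_centrality(G, distance="dist", wf_improved=False).items():
        clo[pos[lab]] = val

    btw = np.zeros(model.p)
    for lab, val in nx.betweenness_centrality(G, weight="dist", normalized=True).items():
        btw[pos[lab]] = val

    cfb = np.zeros(model.p)
    for comp in nx.connected_components(G):
        if len(comp) < 3:
            continue  # no through-flow possible
        sub = G.subgraph(comp)
        vals = nx.current_flow_betweenness_centrality(sub, weight="abs_weight", normalized=True)
        for lab, val in vals.items():
            cfb[pos[lab]] = val
    return {
        "closeness": clo,
        "betweenness": btw,
        "current_flow_betweenness": cfb,
    }


def all_measures(model: GGMResults, test: DataTable | None = None) -> pd.DataFrame:
    """Tidy table of every node measure (plus hold-out predictability if given)."""
    frames = [
        MeasureReport(model.node_labels, "predictability", predictability(model)).to_frame(),
        MeasureReport(model.node_labels, "degree", degree_centrality(model)).to_frame(),
        MeasureReport(
            model.node_labels, "current_flow_closeness", current_flow_closeness(model)
        ).to_frame(),
    ]
    for name, vals in classical_centralities(model).items():
        frames.append(MeasureReport(model.node_labels, name, vals).to_frame())
    if test is not None:
        frames.append(
            MeasureReport(
                model.node_labels,
                "predictability",
                holdout_predictability(model, test),
                context="holdout",
            ).to_frame()
        )
    return pd.concat(frames, ignore_index=True)


MEASURE_FUNCS = {
    "predictability": predictability,
    "degree": degree_centrality,
    "current_flow_closeness": current_flow_closeness,
    "closeness": lambda m: classical_centralities(m)["closeness"],
    "betweenness": lambda m: classical_centralities(m)["betweenness"],
    "current_flow_betweenness": lambda m: classical_centralities(m)["current_flow_betweenness"],
}


# ---------------------------------------------------------------------------
# maximal spanning tree
# ---------------------------------------------------------------------------
def maximal_spanning_tree(model: GGMResults) -> SpanningTree:
    """Maximum-weight spanning forest by Prim's algorithm on |partial corr|.

    Ties are broken lexicographically on the (sorted) node-label pair, making
    the tree deterministic across platforms.  Disconnected networks yield one
    tree per component (a forest); edges carry their signed weights.
    """
    adj = _abs_adjacency(model)
    labels = model.node_labels
    edges: list[tuple[str, str, float]] = []
    total = 0.0
    for comp in _components(adj):
        if len(comp) == 1:
            continue
        # Prim from the lexicographically smallest label in the component
        start = min(comp, key=lambda i: labels[i])
        in_tree = {start}
        remaining = set(comp) - in_tree
        while remaining:
            best = None
            for u in sorted(in_tree, key=lambda i: labels[i]):
                for v in sorted(remaining, key=lambda i: labels[i]):
                    w = adj[u, v]
                    if w <= 0:
                        continue
                    pair = tuple(sorted((labels[u], labels[v])))
                    key = (-w, pair)
                    if best is None or key < best[0]:
                        best = (key, u, v, w)
            _, u, v, w = best
            a, b = sorted((u, v), key=lambda i: labels[i])
            edges.append((labels[a], labels[b], float(model.partial_corr[a, b])))
            total += w
            in_tree.add(v)
            remaining.discard(v)
    edges.sort()
    return SpanningTree(edges=edges, total_weight=float(total))
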