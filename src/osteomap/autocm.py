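"""Auto-Contractive Map and the minimum-spanning-tree semantic map.

The Auto-Contractive Map (Auto-CM) is a three-layer unsupervised network
that learns a many-to-many association structure over the columns of a
[0, 1] data matrix.  Its N input units connect one-to-one ("mono-dedicated")
to N hidden units through weights ``v``, and the hidden layer connects to N
output units through the full matrix ``w``; both weight sets live in
``[0, C]`` where ``C`` is the contraction parameter (default: the number of
columns).  For a record ``x`` the signal is contracted twice:

    hidden:  h_i = x_i * (1 - v_i / C)
    net:     Net_i = sum_j h_j * (1 - w_ij / C)
    output:  o_i = h_i * (1 - Net_i / C)

and the weights move by the contracted residuals (batch mean over records):

    dv_i   = mean_s[ (x_i - h_i) * (1 - v_i / C) ]
    dw_ij  = mean_s[ (h_i - o_i) * (1 - w_ij / C) * h_j ]

``v`` rises monotonically toward ``C``, squeezing the transmitted signal to
zero — training ends when the mean output activation drops below ``tol`` —
while ``w_ij`` integrates the co-activation of columns i and j along the
way.  The update form keeps every weight strictly below ``C``.  Training is
deterministic: weights start at a fixed small constant and records are
presented as one batch per epoch, so the result is invariant to record
order.

Trained weights become distances ``d_ij = 1 - w̄_ij / max(w̄)`` (``w̄`` the
symmetrized matrix), and the minimum spanning tree of the complete distance
graph is the *semantic connectivity map*: each variable is adjacent to the
variables it is most strongly associated with, and edge strength is
reported on the [0, 1] scale ``w̄_ij / max(w̄)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "AutoCMWeights",
    "AutoContractiveMap",
    "AutoCMResults",
    "SemanticGraph",
    "weights_to_distance",
    "minimum_spanning_tree",
    "adjacency_report",
    "semantic_input",
]


@dataclass
class AutoCMWeights:
    """Trained Auto-CM weights."""

    v: np.ndarray  # (N,) input->hidden, mono-dedicated
    w: np.ndarray  # (N, N) hidden->output
    C: float
    epochs: int
    converged: bool
    final_output_activation: float
    columns: list[str]


class AutoContractiveMap:
    """Unsupervised association model over the columns of a [0, 1] matrix.

    Parameters
    ----------
    data : DataFrame or (n, N) array with values in [0, 1]
        Typically the complement-expanded cohort table plus the two outcome
        indicator columns (see :func:`semantic_input`).
    C : float, optional
        Contraction parameter, > 0; defaults to the number of columns.
    """

    #: fixed small initial weight (fraction of C); no random initialization
    INIT_FRACTION = 0.01

    def __init__(self, data, C: float | None = None):
        if hasattr(data, "columns"):
            self.columns = list(data.columns)
            X = data.to_numpy(dtype=float)
        else:
            X = np.asarray(data, dtype=float)
            self.columns = [f"x{j}" for j in range(X.shape[1])]
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("data must be 2D with at least 2 columns")
        if np.any(X < 0) or np.any(X > 1) or not np.all(np.isfinite(X)):
            raise ValueError("Auto-CM inputs must lie in [0, 1]")
        self.X = X
        self.C = float(C) if C is not None else float(X.shape[1])
        if self.C <= 0:
            raise ValueError("contraction parameter C must be positive")

    def fit(self, max_epochs: int = 1000, tol: float = 1e-6) -> "AutoCMResults":
        """Train to contraction; deterministic, record-order invariant."""
        X = self.X
        n, N = X.shape
        C = self.C
        v = np.full(N, self.INIT_FRACTION * C)
        w = np.full((N, N), self.INIT_FRACTION * C)
        mean_out = np.inf
        converged = False
        epoch = 0
        for epoch in range(1, max_epochs + 1):
            h = X * (1.0 - v / C)[None, :]  # (n, N)
            net = h @ (1.0 - w / C).T  # Net_i = sum_j h_j (1 - w_ij/C)
            out = h * (1.0 - net / C)
            dv = np.mean((X - h) * (1.0 - v / C)[None, :], axis=0)
            dw = ((h - out).T @ h) / n * (1.0 - w / C)
            v = v + dv
            w = w + dw
            if not (np.all(v < C) and np.all(w < C)):
                raise RuntimeError("contraction bound violated during training")
            mean_out = float(np.mean(np.abs(out)))
            if mean_out < tol:
                converged = True
                break
        weights = AutoCMWeights(
            v=v,
            w=w,
            C=C,
            epochs=epoch,
            converged=converged,
            final_output_activation=mean_out,
            columns=list(self.columns),
        )
        return AutoCMResults(weights=weights, model=self)


def weights_to_distance(weights: AutoCMWeights) -> np.ndarray:
    """Symmetrized weights mapped to distances in [0, 1].

    ``d_ij = 1 - w̄_ij / max(w̄)`` off-diagonal, ``d_ii = 0``; higher
    association -> smaller distance, and the maximal-weight pair sits at
    distance zero.
    """
    w = np.asarray(weights.w, dtype=float)
    wbar = (w + w.T) / 2.0
    off = ~np.eye(len(wbar), dtype=bool)
    top = wbar[off].max() if off.any() else 0.0
    if top <= 0:
        raise ValueError("weights are untrained (no positive off-diagonal entries)")
    d = 1.0 - wbar / top
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


@dataclass
class SemanticGraph:
    """Minimum spanning tree over variable-association distances.

    ``graph`` is an undirected tree whose edges carry ``strength`` in
    [0, 1] (1 = strongest association) and ``distance``.
    """

    graph: nx.Graph

    def __post_init__(self) -> None:
        g = self.graph
        if g.number_of_nodes() >= 1 and (
            not nx.is_connected(g) or g.number_of_edges() != g.number_of_nodes() - 1
        ):
            raise ValueError("semantic graph must be a spanning tree")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edges(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": t, "strength": d["strength"], "distance": d["distance"]}
            for u, t, d in self.graph.edges(data=True)
        ]
        return (
            pd.DataFrame(rows, columns=["source", "target", "strength", "distance"])
            .sort_values("strength", ascending=False, kind="stable")
            .reset_index(drop=True)
        )

    def total_distance(self) -> float:
        return float(sum(d["distance"] for _, _, d in self.graph.edges(data=True)))

    def neighbors(self, node: str) -> list[tuple[str, float]]:
        if node not in self.graph:
            raise KeyError(f"unknown node {node!r}")
        out = [
            (nbr, self.graph[node][nbr]["strength"]) for nbr in self.graph[node]
        ]
        return sorted(out, key=lambda t: (-t[1], t[0]))

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def write_edgelist_csv(self, path) -> None:
        self.edges().to_csv(path, index=False)

    def write_dot(self, path) -> None:
        lines = ["graph semantic_map {"]
        for u, t, d in self.graph.edges(data=True):
            lines.append(f'  "{u}" -- "{t}" [label="{d["strength"]:.2f}"];')
        lines.append("}")
        Path(path).write_text("\n".join(lines) + "\n")

    def plot(self, ax=None, seed: int = 0):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 8))
        pos = nx.spring_layout(self.graph, seed=seed)
        widths = [1 + 3 * d["strength"] for _, _, d in self.graph.edges(data=True)]
        nx.draw_networkx(
            self.graph, pos=pos, ax=ax, width=widths, node_size=250, font_size=7
        )
        ax.set_axis_off()
        return ax


def minimum_spanning_tree(
    distance: np.ndarray, columns: list[str] | None = None
) -> SemanticGraph:
    """MST of the complete graph on a symmetric distance matrix.

    Kruskal with stable edge ordering: ties in distance break on the edge's
    (row, col) index, so the tree is deterministic.
    """
    d = np.asarray(distance, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.all(np.isfinite(d)):
        raise ValueError("distances must be finite")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    N = d.shape[0]
    names = columns if columns is not None else [f"x{j}" for j in range(N)]
    g = nx.Graph()
    g.add_nodes_from(names)
    for i in range(N):
        for j in range(i + 1, N):
            g.add_edge(
                names[i],
                names[j],
                weight=float(d[i, j]),
                distance=float(d[i, j]),
                strength=float(1.0 - d[i, j]),
            )
    if N == 1:
        return SemanticGraph(graph=g)
    tree = nx.minimum_spanning_tree(g, weight="weight", algorithm="kruskal")
    return SemanticGraph(graph=tree)


def adjacency_report(graph: SemanticGraph, node: str) -> pd.DataFrame:
    """Neighbours of ``node`` in the map, strongest association first."""
    rows = [
        {"neighbor": nbr, "strength": s} for nbr, s in graph.neighbors(node)
    ]
    return pd.DataFrame(rows, columns=["neighbor", "strength"])


def semantic_input(scaled_data: pd.DataFrame, fracture) -> pd.DataFrame:
    """Complement-scaled variables plus the two outcome indicator columns."""
    y = np.asarray(fracture).astype(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("fracture must be binary")
    out = scaled_data.copy()
    out["new_fracture_yes"] = y
    out["new_fracture_no"] = 1.0 - y
    return out


@dataclass
class AutoCMResults:
    """Trained Auto-CM: weights, distances and the semantic map."""

    weights: AutoCMWeights
    model: AutoContractiveMap

    def distance_matrix(self) -> np.ndarray:
        return weights_to_distance(self.weights)

    def mst(self) -> SemanticGraph:
        return minimum_spanning_tree(self.distance_matrix(), self.weights.columns)

    def strength_matrix(self) -> pd.DataFrame:
        d = self.distance_matrix()
        s = 1.0 - d
        np.fill_diagonal(s, 1.0)
        return pd.DataFrame(s, index=self.weights.columns, columns=self.weights.columns)

    def summary(self) -> str:
        w = self.weights
        edges = self.mst().edges()
        lines = [
            "Auto-Contractive Map",
            "====================",
            f"columns: {len(w.columns)}   C = {w.C:g}   epochs = {w.epochs}"
            f"   converged = {w.converged}"
            f"   mean output activation = {w.final_output_activation:.2e}",
            "",
            "strongest semantic-map links:",
        ]
        for _, row in edges.head(8).iterrows():
            lines.append(
                f"  {row.source} -- {row.target}  (strength {row.strength:.3f})"
            )
        return "\n".join(lines)
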