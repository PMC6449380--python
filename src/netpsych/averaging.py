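"""Bootstrap model averaging of learned DAGs.

One structure is learned per bootstrap resample; an undirected skeleton edge's
*strength* is the fraction of replicates containing it in either direction,
and its *direction probability* is the fraction of those occurrences oriented
a given way.  The averaged network retains skeleton edges at or above the
strength threshold (default 0.85) and orients each by its majority direction
(> 0.5 of occurrences).  Because edges are thresholded independently the
result can, in principle, contain a cycle; the repair rule deletes the
lowest-strength edge on a cycle until the graph is acyclic, logging every
deletion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .bn import DagModel, SearchConfig, _as_matrix, hill_climb
from .errors import UnresolvedDirectionError

__all__ = [
    "EdgeStrengthTable",
    "AveragedDag",
    "bootstrap_strengths",
    "average_network",
    "edge_probability_report",
    "AveragedDagResults",
]


@dataclass
class EdgeStrengthTable:
    """Skeleton strengths and orientation tallies from B bootstrap replicates."""

    nodes: list[str]
    B: int
    skeleton_counts: dict[frozenset, int] = field(default_factory=dict)
    direction_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def strength(self, u: str, v: str) -> float:
        return self.skeleton_counts.get(frozenset((u, v)), 0) / self.B

    def direction_prob(self, u: str, v: str) -> float:
        """P(u -> v | skeleton edge u-v present); 0 when the edge never occurs."""
        total = self.skeleton_counts.get(frozenset((u, v)), 0)
        if total == 0:
            return 0.0
        return self.direction_counts.get((u, v), 0) / total

    def pairs(self):
        """All observed skeleton pairs in deterministic lexicographic order."""
        return sorted(tuple(sorted(k)) for k in self.skeleton_counts)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "u": u,
                "v": v,
                "strength": self.strength(u, v),
                "dir_u_to_v": self.direction_prob(u, v),
            }
            for u, v in self.pairs()
        ]
        return pd.DataFrame(rows, columns=["u", "v", "strength", "dir_u_to_v"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class AveragedDag:
    """Thresholded, majority-oriented averaged network."""

    nodes: list[str]
    edges: dict[tuple[str, str], tuple[float, float]]  # (u, v) -> (strength, dir prob)
    strength_threshold: float
    direction_threshold: float
    repaired: list[tuple[str, str, float]] = field(default_factory=list)

    def to_dag_model(self) -> DagModel:
        return DagModel(self.nodes, set(self.edges))

    def to_graphml(self, path) -> None:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (u, v), (s, d) in self.edges.items():
            g.add_edge(u, v, strength=s, direction_prob=d)
        nx.write_graphml(g, path)

    def to_dot(self, path) -> None:
        """DOT export; pen width proportional to the direction probability."""
        lines = ["digraph averaged {"]
        for node in self.nodes:
            lines.append(f'  "{node}";')
        for (u, v), (s, d) in sorted(self.edges.items()):
            lines.append(
                f'  "{u}" -> "{v}" [penwidth={1 + 4 * (d - 0.5):.2f}, '
                f'label="{s:.2f}/{d:.2f}"];'
            )
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def bootstrap_strengths(
    data,
    B: int,
    config: SearchConfig | None = None,
    seed: int = 0,
) -> EdgeStrengthTable:
    """Learn one DAG per bootstrap resample and tally edge occurrences.

    Replicate seeds (for the resample and for the search) are derived
    deterministically from ``seed``; identical arguments give identical
    tables.  A learner failure aborts with the replicate index attached.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    config = config or SearchConfig()
    X, names = _as_matrix(data)
    n = X.shape[0]
    master = np.random.default_rng(seed)
    table = EdgeStrengthTable(nodes=names, B=B)
    for b in range(B):
        rep_seed = int(master.integers(2**31))
        rng = np.random.default_rng(rep_seed)
        rows = rng.integers(n, size=n)
        rep_config = SearchConfig(
            n_restarts=config.n_restarts,
            n_perturbations=config.n_perturbations,
            seed=int(rng.integers(2**31)),
            max_parents=config.max_parents,
        )
        frame = pd.DataFrame(X[rows], columns=names)
        try:
            dag = hill_climb(frame, rep_config)
        except Exception as exc:
            raise type(exc)(f"bootstrap replicate {b}: {exc}") from exc
        for u, v in dag.edges:
            key = frozenset((u, v))
            table.skeleton_counts[key] = table.skeleton_counts.get(key, 0) + 1
            table.direction_counts[(u, v)] = table.direction_counts.get((u, v), 0) + 1
    return table


def average_network(
    table: EdgeStrengthTable,
    strength_threshold: float = 0.85,
    direction_threshold: float = 0.5,
    on_tie: str = "error",
) -> AveragedDag:
    """Threshold an edge-strength table into the final averaged DAG.

    Skeleton edges with strength >= ``strength_threshold`` are retained and
    oriented along their majority direction when its probability exceeds
    ``direction_threshold``.  An exact 50/50 orientation split raises
    :class:`UnresolvedDirectionError` (``on_tie="error"``, the default) or
    drops the edge (``on_tie="drop"`` — a tie never satisfies the strict
    ``> 0.5`` majority rule).  Any residual cycle is repaired by deleting its
    lowest-strength edge (recorded in ``repaired``).
    """
    for name, thr in (("strength", strength_threshold), ("direction", direction_threshold)):
        if not (0 < thr <= 1):
            raise ValueError(f"{name}_threshold must lie in (0, 1]")
    if on_tie not in ("error", "drop"):
        raise ValueError("on_tie must be 'error' or 'drop'")

    edges: dict[tuple[str, str], tuple[float, float]] = {}
    ties = []
    for u, v in table.pairs():
        s = table.strength(u, v)
        if s < strength_threshold:
            continue
        p_uv = table.direction_prob(u, v)
        if p_uv == 0.5:
            ties.append((u, v))
            continue
        if p_uv > 0.5:
            src, dst, p = u, v, p_uv
        else:
            src, dst, p = v, u, 1.0 - p_uv
        if p > direction_threshold:
            edges[(src, dst)] = (s, p)
    if ties and on_tie == "error":
        raise UnresolvedDirectionError(
            f"exact direction tie (probability 0.5) for pairs: {ties}"
        )

    repaired: list[tuple[str, str, float]] = []
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(table.nodes)
    g.add_edges_from(edges)
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        # lowest strength on the cycle; lexicographic tie-break
        victim = min(cycle, key=lambda e: (edges[(e[0], e[1])][0], e[0], e[1]))
        u, v = victim[0], victim[1]
        repaired.append((u, v, edges[(u, v)][0]))
        del edges[(u, v)]
        g.remove_edge(u, v)

    return AveragedDag(
        nodes=list(table.nodes),
        edges=edges,
        strength_threshold=strength_threshold,
        direction_threshold=direction_threshold,
        repaired=repaired,
    )


def _round_half_up_pct(x: float) -> float:
    """Percentage with one decimal, rounding half up (97.25% -> 97.3%)."""
    return float(Decimal(str(x * 100)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def edge_probability_report(avg: AveragedDag) -> pd.DataFrame:
    """CSV-ready per-edge report sorted by strength descending.

    ``strength_pct``/``direction_pct`` are percentages rounded half-up to one
    decimal, the convention used when quoting edge probabilities.
    """
    rows = [
        {
            "source": u,
            "target": v,
            "strength": s,
            "direction_prob": d,
            "strength_pct": _round_half_up_pct(s),
            "direction_pct": _round_half_up_pct(d),
        }
        for (u, v), (s, d) in avg.edges.items()
    ]
    frame = pd.DataFrame(
        rows,
        columns=["source", "target", "strength", "direction_prob",
                 "strength_pct", "direction_pct"],
    )
    if len(frame):
        frame = frame.sort_values(
            ["strength", "source", "target"], ascending=[False, True, True]
        ).reset_index(drop=True)
    return frame


class AveragedDagResults:
    """Results wrapper for a bootstrap-averaged network fit."""

    def __init__(self, model, table: EdgeStrengthTable, averaged: AveragedDag):
        self.model = model
        self.edge_strengths = table
        self.averaged = averaged

    def edge_report(self) -> pd.DataFrame:
        return edge_probability_report(self.averaged)

    def summary(self) -> str:
        avg = self.averaged
        lines = [
            "Bootstrap-averaged Gaussian Bayesian network",
            f"  replicates: {self.edge_strengths.B}   nodes: {len(avg.nodes)}   "
            f"retained edges: {len(avg.edges)}",
            f"  thresholds: strength >= {avg.strength_threshold}, "
            f"direction > {avg.direction_threshold}",
        ]
        if avg.repaired:
            lines.append(f"  cycle repair removed: {avg.repaired}")
        lines.append("")
        lines.append(f"  {'edge':<30}{'strength':>9}{'direction':>10}")
        for (u, v), (s, d) in sorted(
            avg.edges.items(), key=lambda kv: (-kv[1][0], kv[0])
        ):
            lines.append(f"  {u + ' -> ' + v:<30}{s:>9.3f}{d:>10.3f}")
        return "\n".join(lines)
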