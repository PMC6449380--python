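"""Score-based structure learning of linear-Gaussian Bayesian networks.

The learner is greedy BIC hill-climbing over single-edge moves (add, delete,
reverse) with random perturbation restarts.  The score of a DAG decomposes
over nodes; each local term is the Gaussian log-likelihood of the node
regressed on its parents minus a BIC penalty ``(p/2) ln n`` with
``p = |parents| + 2`` (intercept, slopes, residual variance).  Higher is
better.  Likert items are scored as continuous Gaussian variables — an
approximation standard in questionnaire DAG analyses.

The statsmodels-style facade is :class:`GaussianBayesNet`: build it from a
data frame, call :meth:`~GaussianBayesNet.fit` for a single learned DAG with
local parameters, or :meth:`~GaussianBayesNet.fit_averaged` for a
bootstrap-averaged network.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CyclicGraphError, RankDeficiencyError

__all__ = [
    "DagModel",
    "SearchConfig",
    "LocalParams",
    "local_bic",
    "network_bic",
    "hill_climb",
    "enumerate_dags",
    "fit_parameters",
    "GaussianBayesNet",
    "BayesNetResults",
]


# --------------------------------------------------------------------------- #
# data model


@dataclass
class LocalParams:
    """Linear-Gaussian local distribution of one node given its parents."""

    intercept: float
    coefficients: dict[str, float]
    residual_variance: float


@dataclass
class DagModel:
    """A labeled DAG with optional per-node linear-Gaussian parameters."""

    nodes: list[str]
    edges: set[tuple[str, str]] = field(default_factory=set)
    local_params: dict[str, LocalParams] | None = None

    def __post_init__(self):
        self.nodes = list(self.nodes)
        self.edges = set(self.edges)
        idx = set(self.nodes)
        for u, v in self.edges:
            if u not in idx or v not in idx:
                raise ValueError(f"edge ({u}, {v}) references unknown node")
        if not self.is_acyclic():
            raise CyclicGraphError("edge set induces a directed cycle")

    def parents(self, node: str) -> set[str]:
        return {u for u, v in self.edges if v == node}

    def is_acyclic(self) -> bool:
        return _is_acyclic_edgeset(self.nodes, self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    # ---- serialization ---------------------------------------------------- #

    def to_edge_csv(self, path) -> None:
        pd.DataFrame(sorted(self.edges), columns=["source", "target"]).to_csv(
            path, index=False
        )

    @classmethod
    def from_edge_csv(cls, path, nodes: list[str]) -> "DagModel":
        frame = pd.read_csv(path)
        edges = {(str(r.source), str(r.target)) for r in frame.itertuples()}
        return cls(nodes, edges)

    def to_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)

    def to_dot(self, path) -> None:
        lines = ["digraph dag {"]
        for node in self.nodes:
            lines.append(f'  "{node}";')
        for u, v in sorted(self.edges):
            lines.append(f'  "{u}" -> "{v}";')
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


@dataclass
class SearchConfig:
    """Hill-climbing search settings.

    ``n_restarts`` perturb-and-reclimb rounds follow the initial climb from
    the empty graph; each perturbation applies ``n_perturbations`` random
    legal moves to the incumbent optimum.
    """

    n_restarts: int = 5
    n_perturbations: int = 10
    seed: int = 0
    max_parents: int | None = None

    def __post_init__(self):
        if self.n_restarts < 0 or self.n_perturbations < 0:
            raise ValueError("restart/perturbation counts must be >= 0")


# --------------------------------------------------------------------------- #
# scoring


def _as_matrix(data) -> tuple[np.ndarray, list[str]]:
    if hasattr(data, "data"):  # ResponseMatrix
        data = data.data
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), [str(c) for c in data.columns]
    arr = np.asarray(data, dtype=float)
    return arr, [f"x{i}" for i in range(arr.shape[1])]


class _BicScorer:
    """Memoized local BIC terms computed from the centered Gram matrix."""

    def __init__(self, X: np.ndarray, names: list[str]):
        self.n, self.p = X.shape
        self.names = names
        mu = X.mean(axis=0)
        Xc = X - mu
        self.C = Xc.T @ Xc  # centered cross-products; RSS arithmetic below
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def rss(self, j: int, parents: tuple[int, ...]) -> float:
        Cjj = self.C[j, j]
        if not parents:
            return max(Cjj, 0.0)
        S = np.asarray(parents)
        Css = self.C[np.ix_(S, S)]
        c = self.C[S, j]
        try:
            L = np.linalg.cholesky(Css)
        except np.linalg.LinAlgError as exc:
            raise RankDeficiencyError(
                f"collinear parents {[self.names[i] for i in parents]} "
                f"for node {self.names[j]}"
            ) from exc
        # a zero (or numerically zero) pivot means exact collinearity that
        # dpotrf can slip through on the last column
        pivot_tol = math.sqrt(np.finfo(float).eps) * math.sqrt(max(Css.max(), 1e-300))
        if np.min(np.diag(L)) <= pivot_tol:
            raise RankDeficiencyError(
                f"collinear parents {[self.names[i] for i in parents]} "
                f"for node {self.names[j]}"
            )
        w = np.linalg.solve(L, c)
        return max(Cjj - float(w @ w), 0.0)

    def local(self, j: int, parents: frozenset[int] | tuple[int, ...]) -> float:
        key = (j, tuple(sorted(parents)))
        if key in self._cache:
            return self._cache[key]
        rss = self.rss(j, key[1])
        n = self.n
        sigma2 = max(rss / n, np.finfo(float).tiny)
        loglik = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
        k = len(key[1]) + 2  # intercept + slopes + residual variance
        score = loglik - 0.5 * k * math.log(n)
        self._cache[key] = score
        return score


def local_bic(data, node: str, parents) -> float:
    """BIC term of one node given a parent set (higher is better).

    Gaussian log-likelihood of the least-squares regression of ``node`` on
    ``parents`` (ML residual variance), penalized by ``(p/2) ln n`` with
    ``p = |parents| + 2``.
    """
    X, names = _as_matrix(data)
    parents = list(parents)
    if node in parents:
        raise ValueError("a node cannot be its own parent")
    n = X.shape[0]
    if n <= len(parents) + 2:
        raise ValueError("too few observations for this parent set")
    scorer = _BicScorer(X, names)
    j = names.index(node)
    idx = tuple(names.index(p) for p in parents)
    return scorer.local(j, idx)


def network_bic(data, dag: DagModel) -> float:
    """Network score: sum of local BIC terms over all nodes."""
    X, names = _as_matrix(data)
    scorer = _BicScorer(X, names)
    pos = {name: i for i, name in enumerate(names)}
    total = 0.0
    for node in dag.nodes:
        idx = tuple(sorted(pos[p] for p in dag.parents(node)))
        total += scorer.local(pos[node], idx)
    return total


# --------------------------------------------------------------------------- #
# search


def _is_acyclic_edgeset(nodes, edges) -> bool:
    children: dict = {v: [] for v in nodes}
    indeg = {v: 0 for v in nodes}
    for u, v in edges:
        children[u].append(v)
        indeg[v] += 1
    ready = [v for v in nodes if indeg[v] == 0]
    seen = 0
    while ready:
        u = ready.pop()
        seen += 1
        for v in children[u]:
            indeg[v] -= 1
            if indeg[v] == 0:
                ready.append(v)
    return seen == len(list(nodes))


class _SearchState:
    """Parent sets + children adjacency for fast move legality checks."""

    def __init__(self, p: int):
        self.parents = [frozenset() for _ in range(p)]
        self.children = [set() for _ in range(p)]
        self.p = p

    def copy(self) -> "_SearchState":
        out = _SearchState(self.p)
        out.parents = list(self.parents)
        out.children = [set(c) for c in self.children]
        return out

    def has_edge(self, u: int, v: int) -> bool:
        return v in self.children[u]

    def reachable(self, src: int, dst: int, skip_edge=None) -> bool:
        """DFS: is dst reachable from src (optionally ignoring one edge)?"""
        stack = [src]
        seen = {src}
        while stack:
            u = stack.pop()
            if u == dst:
                return True
            for w in self.children[u]:
                if skip_edge is not None and (u, w) == skip_edge:
                    continue
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return False

    def add(self, u: int, v: int) -> None:
        self.parents[v] = self.parents[v] | {u}
        self.children[u].add(v)

    def delete(self, u: int, v: int) -> None:
        self.parents[v] = self.parents[v] - {u}
        self.children[u].discard(v)

    def legal_moves(self, max_parents):
        """All legal moves in deterministic (type, source, target) order."""
        moves = []
        for u in range(self.p):
            for v in range(self.p):
                if u == v:
                    continue
                if self.has_edge(u, v):
                    moves.append(("delete", u, v))
                    # reverse legal iff no alternative path u ~> v
                    if (max_parents is None or len(self.parents[u]) < max_parents) \
                            and not self.reachable(u, v, skip_edge=(u, v)):
                        moves.append(("reverse", u, v))
                elif not self.has_edge(v, u):
                    if (max_parents is None or len(self.parents[v]) < max_parents) \
                            and not self.reachable(v, u):
                        moves.append(("add", u, v))
        order = {"add": 0, "delete": 1, "reverse": 2}
        moves.sort(key=lambda m: (order[m[0]], m[1], m[2]))
        return moves

    def apply(self, move) -> None:
        kind, u, v = move
        if kind == "add":
            self.add(u, v)
        elif kind == "delete":
            self.delete(u, v)
        else:
            self.delete(u, v)
            self.add(v, u)


_IMPROVEMENT_EPS = 1e-9


def _climb(state: _SearchState, scorer: _BicScorer, max_parents) -> float:
    """Greedy best-improvement climb in place; returns the final score."""
    local = [scorer.local(j, state.parents[j]) for j in range(state.p)]
    while True:
        best_delta = _IMPROVEMENT_EPS
        best_move = None
        for move in state.legal_moves(max_parents):
            kind, u, v = move
            try:
                if kind == "add":
                    delta = scorer.local(v, state.parents[v] | {u}) - local[v]
                elif kind == "delete":
                    delta = scorer.local(v, state.parents[v] - {u}) - local[v]
                else:  # reverse u->v  =>  v->u
                    delta = (
                        scorer.local(v, state.parents[v] - {u})
                        - local[v]
                        + scorer.local(u, state.parents[u] | {v})
                        - local[u]
                    )
            except RankDeficiencyError:
                # singular candidate design (e.g. a constant column in a
                # bootstrap resample): the move is treated as illegal
                continue
            if delta > best_delta:
                best_delta = delta
                best_move = move
        if best_move is None:
            return float(sum(local))
        state.apply(best_move)
        kind, u, v = best_move
        local[v] = scorer.local(v, state.parents[v])
        if kind == "reverse":
            local[u] = scorer.local(u, state.parents[u])


def hill_climb(data, config: SearchConfig | None = None) -> DagModel:
    """Learn a DAG by BIC hill-climbing with perturbation restarts.

    Starts from the empty graph, repeatedly applies the best-improving legal
    move, then alternates random perturbations of the incumbent optimum with
    re-climbs.  Returns the highest-scoring DAG encountered.  Deterministic
    given ``config.seed``.
    """
    config = config or SearchConfig()
    X, names = _as_matrix(data)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 observations")
    if p < 2:
        return DagModel(names, set())
    scorer = _BicScorer(X, names)
    rng = np.random.default_rng(config.seed)

    state = _SearchState(p)
    best_score = _climb(state, scorer, config.max_parents)
    best_state = state.copy()

    for _ in range(config.n_restarts):
        cand = best_state.copy()
        for _ in range(config.n_perturbations):
            moves = cand.legal_moves(config.max_parents)
            if not moves:
                break
            move = moves[rng.integers(len(moves))]
            kind, u, v = move
            try:  # probe the post-move parent sets; skip unscoreable moves
                if kind == "add":
                    scorer.local(v, cand.parents[v] | {u})
                elif kind == "reverse":
                    scorer.local(u, cand.parents[u] | {v})
            except RankDeficiencyError:
                continue
            cand.apply(move)
        score = _climb(cand, scorer, config.max_parents)
        if score > best_score + _IMPROVEMENT_EPS:
            best_score = score
            best_state = cand

    edges = {
        (names[u], names[v])
        for u in range(p)
        for v in best_state.children[u]
    }
    return DagModel(names, edges)


def enumerate_dags(node_count: int) -> list[set[tuple[int, int]]]:
    """All labeled DAGs on ``node_count`` <= 4 nodes, as edge sets of index pairs.

    Counts: 1, 3, 25, 543 for 1-4 nodes.  Refuses larger inputs.
    """
    if node_count not in (1, 2, 3, 4):
        raise ValueError("enumerate_dags supports only 1-4 nodes")
    pairs = list(itertools.combinations(range(node_count), 2))
    nodes = list(range(node_count))
    out: list[set[tuple[int, int]]] = []
    for assignment in itertools.product((0, 1, 2), repeat=len(pairs)):
        edges = set()
        for (u, v), a in zip(pairs, assignment):
            if a == 1:
                edges.add((u, v))
            elif a == 2:
                edges.add((v, u))
        if _is_acyclic_edgeset(nodes, edges):
            out.append(edges)
    return out


# --------------------------------------------------------------------------- #
# parameter estimation


def fit_parameters(data, dag: DagModel) -> DagModel:
    """Least-squares linear-Gaussian local parameters for a fixed structure.

    Residual variances are maximum-likelihood (divide by n).  A zero-variance
    node yields residual variance 0 with a degeneracy warning.
    """
    X, names = _as_matrix(data)
    pos = {name: i for i, name in enumerate(names)}
    n = X.shape[0]
    params: dict[str, LocalParams] = {}
    for node in dag.nodes:
        parents = sorted(dag.parents(node))
        y = X[:, pos[node]]
        D = np.column_stack([np.ones(n)] + [X[:, pos[q]] for q in parents])
        G = D.T @ D
        try:
            L = np.linalg.cholesky(G)
        except np.linalg.LinAlgError as exc:
            raise RankDeficiencyError(
                f"singular design for node {node} with parents {parents}"
            ) from exc
        beta = np.linalg.solve(L.T, np.linalg.solve(L, D.T @ y))
        resid = y - D @ beta
        sigma2 = float(resid @ resid) / n
        if sigma2 <= 1e-12:
            warnings.warn(
                f"node {node}: zero residual variance (degenerate local fit)",
                RuntimeWarning,
                stacklevel=2,
            )
            sigma2 = max(sigma2, 0.0)
        params[node] = LocalParams(
            intercept=float(beta[0]),
            coefficients={q: float(b) for q, b in zip(parents, beta[1:])},
            residual_variance=sigma2,
        )
    return DagModel(dag.nodes, set(dag.edges), params)


# --------------------------------------------------------------------------- #
# model facade


class GaussianBayesNet:
    """Linear-Gaussian Bayesian-network model over a wide data table.

    Parameters
    ----------
    data : ResponseMatrix, DataFrame or ndarray
        Observations (rows) by variables (columns).
    var_names : list of str, optional
        Column names when ``data`` is a bare array.

    Examples
    --------
    >>> model = GaussianBayesNet(frame)
    >>> res = model.fit(SearchConfig(seed=1))
    >>> res.dag.edges
    """

    def __init__(self, data, var_names: list[str] | None = None):
        X, names = _as_matrix(data)
        if var_names is not None:
            if len(var_names) != X.shape[1]:
                raise ValueError("var_names length mismatch")
            names = list(var_names)
        self.endog = X
        self.var_names = names
        self.nobs = X.shape[0]

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, columns: list[str] | None = None):
        if columns is not None:
            frame = frame[columns]
        return cls(frame)

    def fit(self, config: SearchConfig | None = None) -> "BayesNetResults":
        """Hill-climb a structure, then estimate local parameters."""
        config = config or SearchConfig()
        frame = pd.DataFrame(self.endog, columns=self.var_names)
        dag = hill_climb(frame, config)
        fitted = fit_parameters(frame, dag)
        score = network_bic(frame, fitted)
        return BayesNetResults(self, fitted, score, config)

    def fit_averaged(
        self,
        B: int = 200,
        config: SearchConfig | None = None,
        strength_threshold: float = 0.85,
        direction_threshold: float = 0.5,
        seed: int = 0,
    ):
        """Bootstrap-averaged network; see :mod:`netpsych.averaging`."""
        from .averaging import AveragedDagResults, average_network, bootstrap_strengths

        frame = pd.DataFrame(self.endog, columns=self.var_names)
        table = bootstrap_strengths(frame, B=B, config=config, seed=seed)
        avg = average_network(table, strength_threshold, direction_threshold)
        return AveragedDagResults(self, table, avg)


class BayesNetResults:
    """Learned structure, local parameters and score of a fitted network."""

    def __init__(self, model: GaussianBayesNet, dag: DagModel, bic: float,
                 config: SearchConfig):
        self.model = model
        self.dag = dag
        self.bic = bic
        self.config = config

    @property
    def params(self) -> dict[str, LocalParams]:
        return self.dag.local_params

    def params_frame(self) -> pd.DataFrame:
        rows = []
        for node in self.dag.nodes:
            lp = self.dag.local_params[node]
            rows.append(
                {
                    "node": node,
                    "parents": ";".join(sorted(lp.coefficients)),
                    "intercept": lp.intercept,
                    "residual_variance": lp.residual_variance,
                    **{f"b[{q}]": c for q, c in lp.coefficients.items()},
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Gaussian Bayesian network (BIC hill-climbing)",
            f"  n obs: {self.model.nobs}   nodes: {len(self.dag.nodes)}   "
            f"edges: {len(self.dag.edges)}",
            f"  network BIC: {self.bic:.3f}",
            f"  restarts: {self.config.n_restarts}   "
            f"perturbations: {self.config.n_perturbations}   seed: {self.config.seed}",
            "",
            f"  {'node':<14}{'parents':<34}{'resid var':>10}",
        ]
        for node in self.dag.nodes:
            lp = self.dag.local_params[node]
            pa = ", ".join(f"{q} ({c:+.3f})" for q, c in sorted(lp.coefficients.items()))
            lines.append(f"  {node:<14}{pa or '-':<34}{lp.residual_variance:>10.4f}")
        return "\n".join(lines)
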