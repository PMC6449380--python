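"""Sparsity selection, hub detection and severity-centrality correlation.

The analysis sparsity K is chosen on three cohort-level criteria evaluated
per participant: small-world organisation (sigma > 1), modular organisation
(Q > 0.3) and connectedness (>= 80% of nodes non-isolated), each required in
at least 95% of participants.  Hubs are nodes ranking in the top 12% of
betweenness (floor(0.12 N) slots) in strictly more than 25% of participants.
Severity-centrality associations are Spearman rank correlations of the three
per-source verbal-abuse totals against the rank-transformed betweenness of
the non-VAQ nodes, Bonferroni-controlled at alpha / m with m the tested node
count (35 when the 15 VAQ nodes are removed from 50).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ContractViolationError,
    UndefinedCorrelationError,
    UndefinedPathLengthError,
)
from .metrics import (
    connectedness_fraction,
    modularity_q,
    normalized_small_world,
)

__all__ = [
    "SparsityCriteria",
    "NullConfig",
    "SparsityReport",
    "HubReport",
    "select_sparsity",
    "detect_hubs",
    "spearman_rho",
    "correlate_severity_centrality",
    "cubic_fit",
]


@dataclass(frozen=True)
class SparsityCriteria:
    """Admissibility thresholds for the sparsity search."""

    sigma_min: float = 1.0
    q_min: float = 0.3
    conn_min: float = 0.80
    participant_frac: float = 0.95


@dataclass(frozen=True)
class NullConfig:
    """Null-model effort for the per-participant metric evaluation."""

    n_nulls: int = 100
    n_modularity_runs: int = 500
    iterations_per_edge: int = 10


@dataclass
class SparsityReport:
    """Per-K admissibility table and the selected analysis sparsity."""

    table: pd.DataFrame  # columns: K, frac_ok, frac_sigma, frac_q, frac_conn, admissible
    selected_k: float | None
    criteria: SparsityCriteria = field(default_factory=SparsityCriteria)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def select_sparsity(
    icns: list[np.ndarray],
    k_grid,
    criteria: SparsityCriteria | None = None,
    null_config: NullConfig | None = None,
    seed: int = 0,
) -> SparsityReport:
    """Evaluate the three admissibility criteria over a K grid.

    For each K, every participant's matrix is proportionally thresholded and
    profiled (sigma, Q, connectedness); K is admissible when the fraction of
    participants satisfying all three criteria reaches
    ``criteria.participant_frac``.  The selected K is the smallest admissible
    grid value (None when the admissible set is empty — an explicit empty
    result, not an exception).
    """
    from .icn import proportional_threshold

    criteria = criteria or SparsityCriteria()
    null_config = null_config or NullConfig()
    if not icns:
        raise ValueError("icn set must be non-empty")
    k_grid = sorted(float(k) for k in k_grid)
    if any(not (0 < k <= 1) for k in k_grid):
        raise ValueError("K grid values must lie in (0, 1]")

    rng = np.random.default_rng(seed)
    rows = []
    for K in k_grid:
        ok = np.zeros(len(icns), dtype=bool)
        sig_ok = np.zeros(len(icns), dtype=bool)
        q_ok = np.zeros(len(icns), dtype=bool)
        conn_ok = np.zeros(len(icns), dtype=bool)
        for i, W in enumerate(icns):
            Wk = proportional_threshold(W, K)
            conn = connectedness_fraction(Wk)
            conn_ok[i] = conn >= criteria.conn_min
            try:
                gm = normalized_small_world(
                    Wk,
                    n_nulls=null_config.n_nulls,
                    seed=int(rng.integers(2**31)),
                    iterations_per_edge=null_config.iterations_per_edge,
                )
                sig_ok[i] = gm.sigma > criteria.sigma_min
            except (UndefinedPathLengthError, ValueError):
                # fragmented or too-sparse graph: small-world criterion fails
                sig_ok[i] = False
            try:
                q = modularity_q(
                    Wk,
                    n_runs=null_config.n_modularity_runs,
                    seed=int(rng.integers(2**31)),
                )
                q_ok[i] = q > criteria.q_min
            except ValueError:
                q_ok[i] = False
            ok[i] = sig_ok[i] and q_ok[i] and conn_ok[i]
        rows.append(
            {
                "K": K,
                "frac_ok": float(ok.mean()),
                "frac_sigma": float(sig_ok.mean()),
                "frac_q": float(q_ok.mean()),
                "frac_conn": float(conn_ok.mean()),
                "admissible": bool(ok.mean() >= criteria.participant_frac),
            }
        )
    table = pd.DataFrame(rows)
    admissible = table.loc[table["admissible"], "K"]
    selected = float(admissible.min()) if len(admissible) else None
    return SparsityReport(table=table, selected_k=selected, criteria=criteria)


@dataclass
class HubReport:
    """Per-node top-rank prevalence and hub flags."""

    table: pd.DataFrame  # columns: node, prevalence, is_hub
    slot_count: int
    top_frac: float
    prevalence_min: float

    @property
    def hubs(self) -> list[str]:
        return self.table.loc[self.table["is_hub"], "node"].tolist()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def detect_hubs(
    profiles: pd.DataFrame,
    top_frac: float = 0.12,
    prevalence_min: float = 0.25,
) -> HubReport:
    """Flag hub nodes from participant x node rank profiles.

    Each participant contributes ``floor(top_frac * N)`` slots filled by
    their highest-ranked nodes (rank ties broken by column order); a node is
    a hub when its slot prevalence strictly exceeds ``prevalence_min``.
    """
    if isinstance(profiles, pd.DataFrame):
        ranks = profiles.to_numpy(dtype=float)
        nodes = [str(c) for c in profiles.columns]
    else:
        ranks = np.asarray(profiles, dtype=float)
        nodes = [f"n{i}" for i in range(ranks.shape[1])]
    n_part, n_nodes = ranks.shape
    slots = math.floor(top_frac * n_nodes)
    counts = np.zeros(n_nodes)
    for row in ranks:
        top = np.argsort(-row, kind="stable")[:slots]
        counts[top] += 1
    prevalence = counts / n_part
    table = pd.DataFrame(
        {
            "node": nodes,
            "prevalence": prevalence,
            "is_hub": prevalence > prevalence_min,
        }
    )
    return HubReport(
        table=table, slot_count=slots, top_frac=top_frac, prevalence_min=prevalence_min
    )


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a t-approximation p-value (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant input vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


#: VAQ-derived column prefixes that must not enter the tested node set.
_VAQ_NODE_PREFIXES = ("VAQavg_", "VAPa_", "VAPeer_", "VAPro_")


def correlate_severity_centrality(
    vaq_totals: pd.DataFrame,
    profiles: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlations of per-source severity with node centralities.

    ``vaq_totals`` carries one column per source; ``profiles`` the rank-
    transformed betweenness of the tested (non-VAQ) nodes.  VAQ nodes in the
    tested set are a contract violation (their association with VAQ totals
    would be auto-regressive).  Bonferroni threshold = ``alpha / m`` with
    ``m`` the tested node count.
    """
    bad = [c for c in profiles.columns if str(c).startswith(_VAQ_NODE_PREFIXES)]
    if bad:
        raise ContractViolationError(f"VAQ nodes must be excluded from the tested set: {bad}")
    if len(vaq_totals) != len(profiles):
        raise ValueError("vaq_totals and profiles must cover the same participants")
    m = profiles.shape[1]
    threshold = alpha / m
    rows = []
    for source in vaq_totals.columns:
        x = vaq_totals[source].to_numpy(dtype=float)
        for node in profiles.columns:
            rho, p = spearman_rho(x, profiles[node].to_numpy(dtype=float))
            rows.append(
                {
                    "source": source,
                    "node": node,
                    "rho": rho,
                    "p": p,
                    "significant": p < threshold,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["m"] = m
    out.attrs["threshold"] = threshold
    return out


def cubic_fit(x, y) -> tuple[np.ndarray, np.ndarray]:
    """Degree-3 least-squares polynomial; returns (coefficients, fitted values).

    Coefficients are in descending power order (``polyfit`` convention).
    Requires at least 4 distinct x values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 4:
        raise ValueError("need >= 4 distinct x values for a cubic fit")
    coeffs = np.polyfit(x, y, deg=3)
    return coeffs, np.polyval(coeffs, x)
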