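"""Sparsity admissibility, hub detection, and severity-centrality correlation."""

import numpy as np
import pandas as pd
import pytest

from netpsych.errors import ContractViolationError, UndefinedCorrelationError
from netpsych.hubs import (
    NullConfig,
    SparsityCriteria,
    correlate_severity_centrality,
    cubic_fit,
    detect_hubs,
    select_sparsity,
    spearman_rho,
)
from netpsych.icn import icn_edges, proportional_threshold
from netpsych.metrics import betweenness, rank_transform


# --------------------------------------------------------------------------- #
# sparsity selection


@pytest.fixture(scope="module")
def icn_cohort():
    rng = np.random.default_rng(0)
    return [icn_edges(rng.standard_normal(50)) for _ in range(6)]


def test_sparsity_search_on_icn_cohort(icn_cohort):
    """Dense-enough K admissible; over-sparse K fails connectedness; smallest picked."""
    report = select_sparsity(
        icn_cohort,
        [0.03, 0.10, 0.21],
        SparsityCriteria(),
        NullConfig(n_nulls=10, n_modularity_runs=20),
        seed=1,
    )
    t = report.table.set_index("K")
    assert not t.loc[0.03, "admissible"]  # fragments below 80% connectedness
    assert t.loc[0.03, "frac_conn"] < 0.95
    assert t.loc[0.10, "admissible"]
    assert t.loc[0.21, "admissible"]
    assert report.selected_k == 0.10


def test_sparsity_no_admissible_k_returns_empty(icn_cohort):
    report = select_sparsity(
        icn_cohort,
        [0.02],
        SparsityCriteria(),
        NullConfig(n_nulls=5, n_modularity_runs=10),
        seed=2,
    )
    assert report.selected_k is None


def test_stricter_participant_fraction_shrinks_admissible_set(icn_cohort):
    base = select_sparsity(
        icn_cohort, [0.05, 0.10], SparsityCriteria(participant_frac=0.5),
        NullConfig(n_nulls=5, n_modularity_runs=10), seed=3,
    )
    strict = select_sparsity(
        icn_cohort, [0.05, 0.10], SparsityCriteria(participant_frac=1.0),
        NullConfig(n_nulls=5, n_modularity_runs=10), seed=3,
    )
    adm_base = set(base.table.loc[base.table["admissible"], "K"])
    adm_strict = set(strict.table.loc[strict.table["admissible"], "K"])
    assert adm_strict <= adm_base


# --------------------------------------------------------------------------- #
# hub detection


def test_hub_slot_arithmetic_at_50_nodes():
    """Top 12% of 50 nodes = 6 slots."""
    profiles = pd.DataFrame(
        [rank_transform(np.arange(50))] * 4, columns=[f"n{i}" for i in range(50)]
    )
    report = detect_hubs(profiles)
    assert report.slot_count == 6


def test_always_top_node_is_hub_and_boundary_is_strict():
    rng = np.random.default_rng(1)
    n_part, n_nodes = 20, 50
    rows = []
    for p in range(n_part):
        vals = rng.random(n_nodes)
        vals[0] = 10.0  # node 0 always dominates
        rows.append(rank_transform(vals))
    profiles = pd.DataFrame(np.vstack(rows), columns=[f"n{i}" for i in range(n_nodes)])
    report = detect_hubs(profiles)
    assert "n0" in report.hubs
    assert report.table.set_index("node").loc["n0", "prevalence"] == 1.0
    # a node in the top set for exactly 25% of participants is NOT a hub
    assert not (report.table["prevalence"] == 0.25).any() or (
        ~report.table.loc[report.table["prevalence"] == 0.25, "is_hub"]
    ).all()


def test_exact_quarter_prevalence_not_flagged():
    # 4 participants, node 0 in the top set exactly once -> prevalence 0.25
    base = np.arange(10, dtype=float)
    rows = [rank_transform(np.roll(base, p)) for p in range(4)]
    profiles = pd.DataFrame(np.vstack(rows), columns=[f"n{i}" for i in range(10)])
    report = detect_hubs(profiles, top_frac=0.12, prevalence_min=0.25)
    assert report.slot_count == 1
    prev = report.table.set_index("node")["prevalence"]
    flagged = report.table.set_index("node")["is_hub"]
    assert not flagged[prev == 0.25].any()


def test_planted_shortest_path_hub_recovered():
    """A node with dominating weights is detected as a hub in >= 95% of cohorts."""
    hits = 0
    n_rep = 20
    for rep in range(n_rep):
        rng = np.random.default_rng(200 + rep)
        rows = []
        N = 50
        for _ in range(12):
            W = rng.uniform(0.05, 0.4, (N, N))
            W = np.triu(W, 1)
            W = W + W.T
            W[0, 1:] = W[1:, 0] = rng.uniform(0.8, 1.0, N - 1)
            np.fill_diagonal(W, 0)
            Wk = proportional_threshold(W, 0.10)
            rows.append(rank_transform(betweenness(Wk)))
        profiles = pd.DataFrame(np.vstack(rows), columns=[f"n{i}" for i in range(N)])
        hits += "n0" in detect_hubs(profiles).hubs
    assert hits >= 0.95 * n_rep


# --------------------------------------------------------------------------- #
# correlation


def test_spearman_monotone_extremes():
    x = np.arange(10.0)
    assert spearman_rho(x, np.exp(x))[0] == pytest.approx(1.0)
    assert spearman_rho(x, -(x**3))[0] == pytest.approx(-1.0)


def test_spearman_with_ties_matches_definitional_oracle():
    rng = np.random.default_rng(4)
    x = rng.integers(0, 4, 60).astype(float)  # heavy ties
    y = x + rng.integers(0, 3, 60)
    rho, p = spearman_rho(x, y)
    # oracle: rank both (tie-averaged), then Pearson from first principles
    rx, ry = rank_transform(x), rank_transform(y)
    rho_oracle = float(
        np.sum((rx - rx.mean()) * (ry - ry.mean()))
        / np.sqrt(np.sum((rx - rx.mean()) ** 2) * np.sum((ry - ry.mean()) ** 2))
    )
    assert rho == pytest.approx(rho_oracle, rel=1e-12)
    assert 0 <= p <= 1


def test_spearman_constant_vector_errors():
    with pytest.raises(UndefinedCorrelationError):
        spearman_rho(np.ones(10), np.arange(10.0))


def test_correlation_table_shape_and_vaq_exclusion(catalog):
    rng = np.random.default_rng(5)
    n = 100
    nodes = [s.name for s in catalog.covariance_net if not s.name.startswith("VAQavg_")]
    assert len(nodes) == 35
    profiles = pd.DataFrame(rng.random((n, 35)), columns=nodes)
    totals = pd.DataFrame(
        rng.random((n, 3)), columns=["VAPa_total", "VAPeer_total", "VAPro_total"]
    )
    table = correlate_severity_centrality(totals, profiles)
    assert len(table) == 3 * 35
    assert table.attrs["m"] == 35
    assert table.attrs["threshold"] == pytest.approx(0.05 / 35)
    with pytest.raises(ContractViolationError):
        bad = profiles.copy()
        bad["VAQavg_01"] = rng.random(n)
        correlate_severity_centrality(totals, bad)


def test_planted_negative_association_is_flagged():
    """Centrality constructed to fall with severity -> large negative rho, significant."""
    rng = np.random.default_rng(6)
    n = 300
    severity = rng.uniform(0, 40, n)
    profiles = pd.DataFrame(
        {"SAS_WD": -severity + rng.normal(0, 5, n), "PHQ_01": rng.random(n)}
    )
    totals = pd.DataFrame({"VAPa_total": severity})
    table = correlate_severity_centrality(totals, profiles).set_index("node")
    assert table.loc["SAS_WD", "rho"] < -0.8
    assert bool(table.loc["SAS_WD", "significant"])


# --------------------------------------------------------------------------- #
# cubic fits


def test_cubic_fit_interpolates_exact_cubic():
    x = np.linspace(-2, 2, 30)
    y = 2 - x + 0.5 * x**2 - 0.25 * x**3
    coeffs, fitted = cubic_fit(x, y)
    assert np.allclose(coeffs, [-0.25, 0.5, -1.0, 2.0], atol=1e-8)
    assert np.allclose(fitted, y, atol=1e-8)


def test_cubic_fit_constant_response():
    x = np.linspace(0, 1, 20)
    coeffs, _ = cubic_fit(x, np.full(20, 3.0))
    assert np.allclose(coeffs[:3], 0.0, atol=1e-10)
    assert coeffs[3] == pytest.approx(3.0)


def test_cubic_fit_noisy_coefficient_recovery():
    rng = np.random.default_rng(7)
    x = rng.uniform(-3, 3, 1000)
    true = np.array([0.5, -1.0, 2.0, 0.3])
    y = np.polyval(true, x) + rng.normal(0, 1.0, 1000)
    coeffs, _ = cubic_fit(x, y)
    X = np.vander(x, 4)
    cov = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))  # sigma = 1
    assert np.all(np.abs(coeffs - true) < 3 * se)


def test_cubic_fit_needs_four_distinct_x():
    with pytest.raises(ValueError):
        cubic_fit([1.0, 1.0, 2.0, 3.0], [0.0, 1.0, 2.0, 3.0])
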