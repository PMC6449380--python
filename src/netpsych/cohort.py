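"""Synthetic questionnaire cohorts with moment-calibrated ordinal marginals.

Each bounded Likert variable is generated as ``clip(round(a*Z + b), lo, hi)``
of a standard-normal latent ``Z``.  The pair ``(a, b)`` is solved numerically
so the analytic mean/SD of the clipped-rounded variable match the published
cohort marginals.  Latents follow a one-general-factor plus
instrument-factor Gaussian model, which induces the positive manifold seen in
questionnaire batteries (all inter-domain correlations weakly positive)
without claiming to estimate the real cohort's joint distribution.

A separate linear-Gaussian structural equation model (:class:`PlantedSem`)
generates continuous data from a known DAG for structure-recovery testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .catalog import ItemCatalog, ItemSpec, build_item_catalog
from .errors import CalibrationInfeasibleError, ConfigError, ValidationError

__all__ = [
    "ResponseMatrix",
    "CorrelationConfig",
    "PlantedSem",
    "calibrate_item",
    "clipped_rounded_moments",
    "simulate_cohort",
    "simulate_planted_sem",
]


class ResponseMatrix:
    """A participant x variable numeric table with optional per-variable bounds.

    Wraps a :class:`pandas.DataFrame`; when item specs are attached the
    constructor enforces the complete-case contract (no missing values) and
    the per-item Likert bounds.
    """

    def __init__(self, data: pd.DataFrame, specs: tuple[ItemSpec, ...] | None = None):
        self.data = data
        self.specs = tuple(specs) if specs is not None else None
        if self.specs is not None:
            names = [s.name for s in self.specs]
            if list(data.columns) != names:
                raise ValidationError(
                    "column order does not match the item specs: "
                    f"{list(data.columns)[:5]}... vs {names[:5]}..."
                )
            self.validate()

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def validate(self) -> None:
        """Check completeness and bounds; raise with offender coordinates."""
        if self.data.isna().any().any():
            bad = [
                (int(i), c)
                for c in self.data.columns
                for i in self.data.index[self.data[c].isna()][:3]
            ]
            raise ValidationError(f"missing values at (row, column): {bad[:10]}")
        if self.specs is None:
            return
        for spec in self.specs:
            col = self.data[spec.name].to_numpy()
            bad_rows = np.nonzero((col < spec.min_value) | (col > spec.max_value))[0]
            if bad_rows.size:
                raise ValidationError(
                    f"value out of bounds [{spec.min_value}, {spec.max_value}] "
                    f"for item {spec.name} at rows {bad_rows[:10].tolist()}"
                )

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def write_metadata(self, path) -> None:
        """Sidecar CSV describing each column (instrument, source, bounds, targets)."""
        if self.specs is None:
            raise ValidationError("no item specs attached")
        pd.DataFrame(
            [
                {
                    "item": s.name,
                    "instrument": s.instrument,
                    "source": s.source,
                    "min": s.min_value,
                    "max": s.max_value,
                    "target_mean": s.target_mean,
                    "target_sd": s.target_sd,
                }
                for s in self.specs
            ]
        ).to_csv(path, index=False)


def clipped_rounded_moments(a: float, b: float, lo: float, hi: float) -> tuple[float, float]:
    """Analytic mean and SD of ``clip(round(a*Z + b), lo, hi)`` for Z ~ N(0, 1).

    The support is the integer grid ``lo..hi``; cell probabilities are normal
    CDF differences at half-integer break points, with the end cells absorbing
    the clipped tails.
    """
    grid = np.arange(int(lo), int(hi) + 1, dtype=float)
    upper = np.minimum((grid + 0.5 - b) / a, np.inf)
    lower = (grid - 0.5 - b) / a
    cdf_up = stats.norm.cdf(upper)
    cdf_lo = stats.norm.cdf(lower)
    p = cdf_up - cdf_lo
    p[0] = cdf_up[0]  # lower tail absorbed
    p[-1] = 1.0 - cdf_lo[-1]  # upper tail absorbed
    mean = float(np.sum(grid * p))
    var = float(np.sum((grid - mean) ** 2 * p))
    return mean, math.sqrt(max(var, 0.0))


#: Calibration tolerances on the achieved analytic moments.
_MEAN_TOL = 0.02
_SD_TOL = 0.05


def calibrate_item(spec: ItemSpec) -> tuple[float, float]:
    """Solve for the latent transform ``(a, b)`` matching an item's target moments.

    Returns ``(scale, shift)`` such that ``clip(round(a*Z + b), lo, hi)`` has
    analytic mean within 0.02 and SD within 0.05 of the targets.  Raises
    :class:`CalibrationInfeasibleError` when no transform achieves that, e.g.
    for a target SD the bounded support cannot carry.
    """
    if spec.target_sd <= 0:
        raise CalibrationInfeasibleError(f"{spec.name}: target SD must be positive")
    lo, hi = spec.min_value, spec.max_value
    m0, s0 = spec.target_mean, spec.target_sd

    def residual(x):
        a, b = math.exp(x[0]), x[1]
        m, s = clipped_rounded_moments(a, b, lo, hi)
        return [m - m0, s - s0]

    best = None
    # a few starts: moment-matched affine plus spread/shifted variants for
    # heavily clipped (zero-inflated) items
    starts = [
        (math.log(max(s0, 0.05)), m0),
        (math.log(max(2 * s0, 0.1)), m0 - s0),
        (math.log(max(3 * s0, 0.2)), m0 - 2 * s0),
        (math.log(max(s0 / 2, 0.05)), m0 + s0 / 2),
    ]
    for x0 in starts:
        sol = optimize.least_squares(residual, x0=list(x0), xtol=1e-14, ftol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.cost < 1e-16:
            break
    a, b = math.exp(best.x[0]), best.x[1]
    m, s = clipped_rounded_moments(a, b, lo, hi)
    if abs(m - m0) > _MEAN_TOL or abs(s - s0) > _SD_TOL:
        raise CalibrationInfeasibleError(
            f"{spec.name}: cannot reach mean {m0:.3f} / SD {s0:.3f} on "
            f"[{lo}, {hi}] (best achieved {m:.3f} / {s:.3f})"
        )
    return a, b


@dataclass(frozen=True)
class CorrelationConfig:
    """Latent correlation structure: one general factor plus instrument factors.

    Latent for item i in instrument group g:
    ``z_i = g_load*G + f_load*F_g + sqrt(1 - g_load^2 - f_load^2)*eps_i``.
    The three VAQ sources form three separate instrument groups.  Loadings
    must satisfy ``g_load^2 + f_load^2 < 1`` for a positive-definite latent
    correlation.
    """

    general_loading: float = 0.5
    instrument_loading: float = 0.4

    def __post_init__(self):
        uniq = 1.0 - self.general_loading**2 - self.instrument_loading**2
        if uniq <= 0:
            raise ConfigError(
                "general_loading^2 + instrument_loading^2 must be < 1 "
                f"(got uniqueness {uniq:.3f})"
            )

    @property
    def uniqueness(self) -> float:
        return 1.0 - self.general_loading**2 - self.instrument_loading**2


def _group_key(spec: ItemSpec) -> tuple[str, str]:
    return (spec.instrument, spec.source)


def simulate_cohort(
    n: int,
    catalog: ItemCatalog | None = None,
    correlation: CorrelationConfig | None = None,
    seed: int = 0,
) -> ResponseMatrix:
    """Simulate ``n`` questionnaire respondents over the 83 catalog items.

    Deterministic given ``seed``.  Every value lies within its item's bounds;
    item marginals match their calibrated targets in expectation.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    catalog = catalog or build_item_catalog()
    correlation = correlation or CorrelationConfig()
    specs = catalog.simulated
    rng = np.random.default_rng(seed)

    groups = sorted({_group_key(s) for s in specs})
    g_idx = {g: i for i, g in enumerate(groups)}
    general = rng.standard_normal(n)
    factors = rng.standard_normal((n, len(groups)))
    eps = rng.standard_normal((n, len(specs)))

    gl, fl = correlation.general_loading, correlation.instrument_loading
    resid = math.sqrt(correlation.uniqueness)

    cols = {}
    for j, spec in enumerate(specs):
        z = gl * general + fl * factors[:, g_idx[_group_key(spec)]] + resid * eps[:, j]
        a, b = calibrate_item(spec)
        x = np.clip(np.round(a * z + b), spec.min_value, spec.max_value)
        cols[spec.name] = x
    frame = pd.DataFrame(cols, columns=[s.name for s in specs])
    return ResponseMatrix(frame, specs)


@dataclass
class PlantedSem:
    """Linear-Gaussian structural equation model with a known DAG.

    ``adjacency[i, j] = 1`` encodes the edge ``nodes[i] -> nodes[j]``;
    ``coefficients`` carries the matching path weights, ``noise_sd`` the
    per-node residual scales.
    """

    nodes: list[str]
    adjacency: np.ndarray
    coefficients: np.ndarray
    noise_sd: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        p = len(self.nodes)
        self.adjacency = np.asarray(self.adjacency, dtype=int)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.noise_sd is None:
            self.noise_sd = np.ones(p)
        self.noise_sd = np.asarray(self.noise_sd, dtype=float)
        if self.adjacency.shape != (p, p) or self.coefficients.shape != (p, p):
            raise ConfigError("adjacency/coefficients must be p x p")
        if np.any(self.noise_sd <= 0):
            raise ConfigError("noise_sd must be positive")
        if self.topological_order() is None:
            raise ConfigError("adjacency matrix is cyclic")

    @classmethod
    def chain(cls, names: list[str], coef: float = 0.7, noise_sd: float = 1.0) -> "PlantedSem":
        """A directed chain ``names[0] -> names[1] -> ...`` with equal weights."""
        p = len(names)
        adj = np.zeros((p, p), dtype=int)
        coefs = np.zeros((p, p))
        for i in range(p - 1):
            adj[i, i + 1] = 1
            coefs[i, i + 1] = coef
        return cls(list(names), adj, coefs, np.full(p, noise_sd))

    def topological_order(self) -> list[int] | None:
        """Kahn's algorithm; None when the adjacency has a cycle."""
        p = len(self.nodes)
        indeg = self.adjacency.sum(axis=0).copy()
        ready = [i for i in range(p) if indeg[i] == 0]
        order: list[int] = []
        while ready:
            i = ready.pop()
            order.append(i)
            for j in np.nonzero(self.adjacency[i])[0]:
                indeg[j] -= 1
                if indeg[j] == 0:
                    ready.append(int(j))
        return order if len(order) == p else None

    def implied_covariance(self) -> np.ndarray:
        """Model-implied covariance ``(I - B)^-T D (I - B)^-1``.

        ``B`` is the coefficient matrix (B[i, j] = weight of i -> j) and
        ``D`` the diagonal of residual variances.
        """
        p = len(self.nodes)
        B = self.coefficients * self.adjacency
        inv = np.linalg.inv(np.eye(p) - B)
        return inv.T @ np.diag(self.noise_sd**2) @ inv


def simulate_planted_sem(sem: PlantedSem, n: int, seed: int = 0) -> ResponseMatrix:
    """Draw ``n`` continuous observations from a planted linear-Gaussian SEM.

    Values are generated in topological order (node = sum of parent
    contributions + Gaussian noise); no bounds apply.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    order = sem.topological_order()
    if order is None:  # __post_init__ already rejects, but re-check defensively
        raise ConfigError("adjacency matrix is cyclic")
    rng = np.random.default_rng(seed)
    p = len(sem.nodes)
    X = np.zeros((n, p))
    noise = rng.standard_normal((n, p)) * sem.noise_sd
    for j in order:
        parents = np.nonzero(sem.adjacency[:, j])[0]
        X[:, j] = noise[:, j]
        for i in parents:
            X[:, j] += sem.coefficients[i, j] * X[:, i]
    return ResponseMatrix(pd.DataFrame(X, columns=sem.nodes))
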