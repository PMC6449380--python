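"""End-to-end pipeline orchestration and file-format plumbing.

Stages (in order): ``simulate`` -> ``network1`` (three per-source item DAGs)
-> ``network2`` (41-node severity DAG) -> ``icn`` (covariance networks,
metrics, sparsity search, centrality profiles) -> ``hubs`` -> ``correlate``.
Every run writes a ``manifest.json`` recording package version, master seed,
derived stage seeds, all numeric thresholds and per-stage timings, plus a
plain-text ``run.log``.  Runs are deterministic under a fixed master seed;
stage seeds are derived by spawning a ``numpy`` ``SeedSequence`` keyed on the
stage index.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .averaging import average_network, bootstrap_strengths, edge_probability_report
from .bn import SearchConfig
from .catalog import ItemCatalog, VAQ_SOURCES, build_item_catalog
from .cohort import CorrelationConfig, ResponseMatrix, simulate_cohort
from .errors import ValidationError
from .hubs import (
    NullConfig,
    SparsityCriteria,
    correlate_severity_centrality,
    detect_hubs,
    select_sparsity,
)
from .icn import icn_edges, network3_features, proportional_threshold, zscore_features
from .metrics import (
    betweenness,
    connectedness_fraction,
    modularity_q,
    normalized_small_world,
    rank_transform,
)

__all__ = ["RunConfig", "read_responses", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("simulate", "network1", "network2", "icn", "hubs", "correlate")

_SOURCE_PREFIX = {"parents": "VAPa", "peers": "VAPeer", "supervisors": "VAPro"}


@dataclass
class RunConfig:
    """All knobs of one pipeline run.

    Thresholds default to the study constants: edge strength retention 0.85,
    direction majority 0.5, small-worldness > 1, modularity > 0.3,
    connectedness >= 0.80 in >= 95% of participants, hub slots = top 12%,
    hub prevalence > 25%, alpha 0.05 Bonferroni-split over tested nodes.
    """

    outdir: str = "netpsych_run"
    stages: tuple[str, ...] = ALL_STAGES
    input_csv: str | None = None  # read instead of simulating
    n_participants: int = 500
    seed: int = 0
    bootstraps: int = 200
    n_restarts: int = 5
    n_perturbations: int = 10
    strength_threshold: float = 0.85
    direction_threshold: float = 0.5
    k_grid: tuple[float, ...] = (0.10, 0.12, 0.15, 0.18, 0.21)
    analysis_k: float | None = None  # default: smallest admissible
    n_nulls: int = 100
    n_modularity_runs: int = 500
    sigma_min: float = 1.0
    q_min: float = 0.3
    conn_min: float = 0.80
    participant_frac: float = 0.95
    top_frac: float = 0.12
    prevalence_min: float = 0.25
    alpha: float = 0.05
    general_loading: float = 0.5
    instrument_loading: float = 0.4
    sparsity_participants: int | None = 50  # subsample for the K search; None = all

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for name, val, lo, hi in [
            ("strength_threshold", self.strength_threshold, 0, 1),
            ("direction_threshold", self.direction_threshold, 0, 1),
            ("top_frac", self.top_frac, 0, 1),
            ("prevalence_min", self.prevalence_min, 0, 1),
            ("alpha", self.alpha, 0, 1),
            ("participant_frac", self.participant_frac, 0, 1),
        ]:
            if not (lo < val <= hi):
                raise ValueError(f"{name} must lie in ({lo}, {hi}]")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed: SeedSequence(master).spawn by stage index."""
        idx = ALL_STAGES.index(stage)
        ss = np.random.SeedSequence(self.seed, spawn_key=(idx,))
        return int(ss.generate_state(1)[0] % (2**31))


def read_responses(path, catalog: ItemCatalog | None = None) -> ResponseMatrix:
    """Read and validate a wide response CSV against the item catalog.

    The header must match the 83 simulated catalog items exactly; unknown or
    missing columns, missing values and bound violations raise
    :class:`ValidationError` naming the offenders.
    """
    catalog = catalog or build_item_catalog()
    frame = pd.read_csv(path)
    expected = [s.name for s in catalog.simulated]
    extra = [c for c in frame.columns if c not in expected]
    missing = [c for c in expected if c not in frame.columns]
    if extra:
        raise ValidationError(f"unknown columns: {extra}")
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    frame = frame[expected]
    return ResponseMatrix(frame, catalog.simulated)


def _vaq_totals(frame: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for src in VAQ_SOURCES:
        prefix = _SOURCE_PREFIX[src]
        cols = [f"{prefix}_{i:02d}" for i in range(1, 16)]
        out[f"{prefix}_total"] = frame[cols].sum(axis=1)
    return pd.DataFrame(out, index=frame.index)


def _network2_frame(frame: pd.DataFrame, catalog: ItemCatalog) -> pd.DataFrame:
    totals = _vaq_totals(frame)
    cols = {}
    for spec in catalog.severity_dag:
        if spec.name.endswith("_total"):
            cols[spec.name] = totals[spec.name]
        else:
            cols[spec.name] = frame[spec.name]
    return pd.DataFrame(cols, columns=[s.name for s in catalog.severity_dag])


def _setup_logger(outdir: Path) -> logging.Logger:
    logger = logging.getLogger(f"netpsych.run.{outdir}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s",
                            datefmt="%Y-%m-%dT%H:%M:%S")
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(fmt)
    logger.addHandler(fh)
    return logger


def run_pipeline(config: RunConfig) -> Path:
    """Execute the selected stages and write all artifacts under ``outdir``.

    Returns the run directory.  A stage failure aborts with the failing stage
    named; artifacts of completed stages are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger = _setup_logger(outdir)
    catalog = build_item_catalog()
    manifest: dict = {
        "package": "netpsych",
        "version": "0.1.0",
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "stage_seeds": {s: config.stage_seed(s) for s in ALL_STAGES},
        "stages_run": [],
        "timings_s": {},
    }
    state: dict = {}

    def _run_stage(name, fn):
        t0 = time.perf_counter()
        logger.info("stage %s: start", name)
        try:
            fn()
        except Exception as exc:
            logger.error("stage %s: FAILED: %s", name, exc)
            _write_manifest(outdir, manifest)
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        dt = time.perf_counter() - t0
        manifest["stages_run"].append(name)
        manifest["timings_s"][name] = round(dt, 3)
        logger.info("stage %s: done in %.2fs", name, dt)

    # ---- simulate / load -------------------------------------------------- #
    def _stage_simulate():
        if config.input_csv is not None:
            rm = read_responses(config.input_csv, catalog)
            logger.info("loaded %d participants from %s", rm.n, config.input_csv)
        else:
            rm = simulate_cohort(
                config.n_participants,
                catalog,
                CorrelationConfig(config.general_loading, config.instrument_loading),
                seed=config.stage_seed("simulate"),
            )
            logger.info("simulated %d participants", rm.n)
        rm.to_csv(outdir / "cohort.csv")
        rm.write_metadata(outdir / "item_metadata.csv")
        state["cohort"] = rm

    def _ensure_cohort():
        if "cohort" not in state:
            path = outdir / "cohort.csv"
            if config.input_csv is not None:
                state["cohort"] = read_responses(config.input_csv, catalog)
            elif path.exists():
                state["cohort"] = read_responses(path, catalog)
                logger.info("reusing cached cohort at %s", path)
            else:
                raise ValidationError(
                    "no cohort available: run the simulate stage or provide input_csv"
                )
        return state["cohort"]

    # ---- network 1: per-source item DAGs ---------------------------------- #
    def _stage_network1():
        rm = _ensure_cohort()
        seed = config.stage_seed("network1")
        sc = SearchConfig(config.n_restarts, config.n_perturbations)
        for k, src in enumerate(VAQ_SOURCES):
            cols = [f"{_SOURCE_PREFIX[src]}_{i:02d}" for i in range(1, 16)]
            table = bootstrap_strengths(
                rm.data[cols], B=config.bootstraps, config=sc, seed=seed + k
            )
            avg = average_network(
                table, config.strength_threshold, config.direction_threshold,
                on_tie="drop",
            )
            table.to_csv(outdir / f"network1_{src}_strengths.csv")
            edge_probability_report(avg).to_csv(
                outdir / f"network1_{src}_edges.csv", index=False
            )
            avg.to_graphml(outdir / f"network1_{src}.graphml")
            avg.to_dot(outdir / f"network1_{src}.dot")
            logger.info("network1[%s]: %d retained edges", src, len(avg.edges))

    # ---- network 2: severity DAG ------------------------------------------ #
    def _stage_network2():
        rm = _ensure_cohort()
        frame = _network2_frame(rm.data, catalog)
        table = bootstrap_strengths(
            frame,
            B=config.bootstraps,
            config=SearchConfig(config.n_restarts, config.n_perturbations),
            seed=config.stage_seed("network2"),
        )
        avg = average_network(
            table, config.strength_threshold, config.direction_threshold,
            on_tie="drop",
        )
        table.to_csv(outdir / "network2_strengths.csv")
        edge_probability_report(avg).to_csv(outdir / "network2_edges.csv", index=False)
        avg.to_graphml(outdir / "network2.graphml")
        avg.to_dot(outdir / "network2.dot")
        logger.info("network2: %d retained edges", len(avg.edges))

    # ---- icn: covariance networks, sparsity search, profiles -------------- #
    def _stage_icn():
        rm = _ensure_cohort()
        feats = network3_features(rm.data, catalog)
        z = zscore_features(feats)
        zvals = z.to_numpy()
        icns = [icn_edges(row) for row in zvals]
        seed = config.stage_seed("icn")
        crit = SparsityCriteria(
            config.sigma_min, config.q_min, config.conn_min, config.participant_frac
        )
        nulls = NullConfig(config.n_nulls, config.n_modularity_runs)
        sub = icns
        if (
            config.sparsity_participants is not None
            and len(icns) > config.sparsity_participants
        ):
            pick = np.random.default_rng(seed).choice(
                len(icns), config.sparsity_participants, replace=False
            )
            sub = [icns[i] for i in sorted(pick)]
        report = select_sparsity(sub, config.k_grid, crit, nulls, seed=seed)
        report.to_csv(outdir / "sparsity_report.csv")
        k = config.analysis_k if config.analysis_k is not None else report.selected_k
        if k is None:
            k = min(config.k_grid)
            logger.warning("no admissible K; falling back to grid minimum %.3f", k)
        manifest["analysis_k"] = k
        logger.info("analysis sparsity K = %.3f", k)

        rng = np.random.default_rng(seed + 1)
        nodes = list(feats.columns)
        prof_rows = []
        metric_rows = []
        for i, W in enumerate(icns):
            Wk = proportional_threshold(W, k)
            prof_rows.append(rank_transform(betweenness(Wk)))
            gm = normalized_small_world(
                Wk, n_nulls=min(config.n_nulls, 20), seed=int(rng.integers(2**31))
            )
            q = modularity_q(
                Wk, n_runs=min(config.n_modularity_runs, 50),
                seed=int(rng.integers(2**31)),
            )
            metric_rows.append(
                {
                    "participant": i,
                    "gamma": gm.gamma,
                    "lambda": gm.lam,
                    "sigma": gm.sigma,
                    "Q": q,
                    "connectedness": connectedness_fraction(Wk),
                }
            )
        profiles = pd.DataFrame(np.vstack(prof_rows), columns=nodes)
        profiles.insert(0, "participant", range(len(profiles)))
        profiles.to_csv(outdir / "centrality_profiles.csv", index=False)
        pd.DataFrame(metric_rows).to_csv(outdir / "participant_metrics.csv", index=False)
        state["profiles"] = profiles
        logger.info("icn: %d profiles at K=%.3f", len(profiles), k)

    def _ensure_profiles() -> pd.DataFrame:
        if "profiles" not in state:
            path = outdir / "centrality_profiles.csv"
            if not path.exists():
                raise ValidationError("no centrality profiles: run the icn stage first")
            state["profiles"] = pd.read_csv(path)
            logger.info("reusing cached profiles at %s", path)
        return state["profiles"]

    # ---- hubs -------------------------------------------------------------- #
    def _stage_hubs():
        profiles = _ensure_profiles().drop(columns=["participant"])
        report = detect_hubs(profiles, config.top_frac, config.prevalence_min)
        report.to_csv(outdir / "hubs.csv")
        manifest["hub_slot_count"] = report.slot_count
        manifest["hubs"] = report.hubs
        logger.info("hubs: slots=%d, flagged=%s", report.slot_count, report.hubs)

    # ---- severity correlations --------------------------------------------- #
    def _stage_correlate():
        rm = _ensure_cohort()
        profiles = _ensure_profiles().drop(columns=["participant"])
        tested = profiles[[c for c in profiles.columns if not c.startswith("VAQavg_")]]
        totals = _vaq_totals(rm.data)
        table = correlate_severity_centrality(totals, tested, alpha=config.alpha)
        table.to_csv(outdir / "correlations.csv", index=False)
        manifest["correlation_m"] = int(table.attrs["m"])
        manifest["correlation_threshold"] = float(table.attrs["threshold"])
        logger.info(
            "correlate: m=%d tests per source, threshold=%.5f, %d significant",
            table.attrs["m"], table.attrs["threshold"], int(table["significant"].sum()),
        )

    stage_fns = {
        "simulate": _stage_simulate,
        "network1": _stage_network1,
        "network2": _stage_network2,
        "icn": _stage_icn,
        "hubs": _stage_hubs,
        "correlate": _stage_correlate,
    }
    for stage in ALL_STAGES:
        if stage in config.stages:
            _run_stage(stage, stage_fns[stage])

    _write_manifest(outdir, manifest)
    logger.info("run complete: %s", ", ".join(manifest["stages_run"]))
    return outdir


def _write_manifest(outdir: Path, manifest: dict) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
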