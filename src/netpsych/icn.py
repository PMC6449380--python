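"""Intra-individual covariance networks (ICNs).

Features are z-scored against cohort-wide (population) means and SDs; for a
single participant the edge weight between features i and j is

    w(i, j) = 1 / exp((z_i - z_j)^2) = exp(-(z_i - z_j)^2),

a similarity in (0, 1] that equals 1 exactly when the two z-scores coincide.
Each participant's symmetric weight matrix is proportionally thresholded to a
target sparsity K, keeping only the round(K * N(N-1)/2) strongest edges with
their weights preserved.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .catalog import ItemCatalog, build_item_catalog
from .errors import DegenerateFeatureError, ValidationError

__all__ = [
    "zscore_features",
    "icn_edges",
    "proportional_threshold",
    "vaq_source_average",
    "network3_features",
    "export_icn",
]

_VAQ_PREFIXES = ("VAPa", "VAPeer", "VAPro")


def _as_frame(data) -> pd.DataFrame:
    return data.data if hasattr(data, "data") else data


def vaq_source_average(data) -> pd.DataFrame:
    """Average the 15 VAQ items over the three sources.

    Requires all 45 per-source columns (``VAPa_xx``, ``VAPeer_xx``,
    ``VAPro_xx``); returns ``VAQavg_01`` .. ``VAQavg_15``.
    """
    frame = _as_frame(data)
    out = {}
    for no in range(1, 16):
        cols = [f"{p}_{no:02d}" for p in _VAQ_PREFIXES]
        missing = [c for c in cols if c not in frame.columns]
        if missing:
            raise ValidationError(f"missing VAQ source columns: {missing}")
        out[f"VAQavg_{no:02d}"] = frame[cols].mean(axis=1)
    return pd.DataFrame(out, index=frame.index)


def network3_features(data, catalog: ItemCatalog | None = None) -> pd.DataFrame:
    """Assemble the 50 covariance-network features from simulated items.

    Source-averaged VAQ items, then the PHQ/GAD/LSAS/SAS columns, the CAGE
    total, and the ASRS items, in catalog order.
    """
    catalog = catalog or build_item_catalog()
    frame = _as_frame(data)
    avg = vaq_source_average(frame)
    cage_cols = [f"CAGE_no_{i}" for i in range(1, 5)]
    missing = [c for c in cage_cols if c not in frame.columns]
    if missing:
        raise ValidationError(f"missing CAGE columns: {missing}")
    pieces = {**{c: avg[c] for c in avg.columns}}
    for spec in catalog.covariance_net:
        if spec.name.startswith("VAQavg_"):
            continue
        if spec.name == "CAGE_total":
            pieces[spec.name] = frame[cage_cols].sum(axis=1)
        else:
            if spec.name not in frame.columns:
                raise ValidationError(f"missing feature column: {spec.name}")
            pieces[spec.name] = frame[spec.name]
    return pd.DataFrame(pieces, columns=[s.name for s in catalog.covariance_net])


def zscore_features(features: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scores using cohort-wide population moments (divide by n).

    A zero-variance feature cannot be standardized and raises
    :class:`DegenerateFeatureError` naming it.
    """
    frame = _as_frame(features)
    values = frame.to_numpy(dtype=float)
    mu = values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    dead = np.nonzero(sd == 0)[0]
    if dead.size:
        names = [frame.columns[i] for i in dead]
        raise DegenerateFeatureError(f"zero-variance feature(s): {names}")
    z = (values - mu) / sd
    return pd.DataFrame(z, index=frame.index, columns=frame.columns)


def icn_edges(z_row: np.ndarray) -> np.ndarray:
    """One participant's ICN: ``w(i, j) = exp(-(z_i - z_j)^2)``, zero diagonal."""
    z = np.asarray(z_row, dtype=float).ravel()
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite z-scores")
    diff = z[:, None] - z[None, :]
    W = np.exp(-(diff**2))
    np.fill_diagonal(W, 0.0)
    return W


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def proportional_threshold(W: np.ndarray, K: float) -> np.ndarray:
    """Keep the ``round(K * N(N-1)/2)`` strongest edges; zero the rest.

    Weights are preserved (not binarized); the edge count uses
    round-half-away-from-zero, and ties at the cutoff are broken by
    lexicographic (i, j) order so thresholding is deterministic and nested
    across K.
    """
    if not (0 < K <= 1):
        raise ValueError("K must lie in (0, 1]")
    W = np.asarray(W, dtype=float)
    N = W.shape[0]
    m = _round_half_away(K * N * (N - 1) / 2)
    iu, ju = np.triu_indices(N, k=1)
    w = W[iu, ju]
    # sort by (-weight, i, j): strongest first, deterministic at ties
    order = np.lexsort((ju, iu, -w))
    keep = order[:m]
    out = np.zeros_like(W)
    out[iu[keep], ju[keep]] = w[keep]
    out += out.T
    return out


def export_icn(W: np.ndarray, node_names: list[str], path_edges, path_dense=None) -> None:
    """Write one participant's matrix as an edge list CSV (i, j, weight).

    Optionally also as a dense labeled matrix CSV.
    """
    iu, ju = np.triu_indices(W.shape[0], k=1)
    mask = W[iu, ju] != 0
    pd.DataFrame(
        {
            "i": [node_names[a] for a in iu[mask]],
            "j": [node_names[b] for b in ju[mask]],
            "weight": W[iu[mask], ju[mask]],
        }
    ).to_csv(path_edges, index=False)
    if path_dense is not None:
        pd.DataFrame(W, index=node_names, columns=node_names).to_csv(path_dense)
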