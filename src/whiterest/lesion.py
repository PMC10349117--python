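"""WhiteRest scoring: disconnectome, DiscROver and Presence scores.

A lesion mask is converted into a *disconnectome* — a per-voxel probability
that the lesion disconnects the white-matter pathways through that voxel —
using the structural connectivity priors.  The impact of the lesion on each
resting-state network is then quantified by the DiscROver score

    DiscROver(RSN, Disco) = 100 * sum_{v in RSN} Z_RSN(v) * P_Disco(v)
                                / sum_{v in RSN} Z_RSN(v)

where membership ``v in RSN`` means the network's white-matter z-map exceeds
the atlas threshold at v.  0 means the lesion touches none of the network's
white matter; 100 means it impacts all of it.

The disconnectome here is a prior-based surrogate for streamline-based
disconnection tracking: it reads the connection-probability table
symmetrically and assigns each voxel the probability of its strongest
connection into the lesion.  Lesion voxels themselves get probability 1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .atlas import DEFAULT_Z_THR, RSNMapPair
from .projection import ConnectivityPriors
from .volumes import Volume, assert_same_grid

__all__ = [
    "DisconnectomeMap",
    "compute_disconnectome",
    "discrover",
    "presence_scores",
    "score_report",
]

logger = logging.getLogger(__name__)

DisconnectomeMap = Volume  # probabilities in [0, 1]


def _sparse_col_max(mat) -> np.ndarray:
    """Max over rows for each column of a sparse matrix, as a dense vector."""
    if mat.shape[0] == 0:
        return np.zeros(mat.shape[1])
    return np.asarray(mat.max(axis=0).todense()).ravel()


def _sparse_col_union(mat) -> np.ndarray:
    """Probabilistic union 1 - prod(1 - p) over rows, per column (dense)."""
    if mat.shape[0] == 0:
        return np.zeros(mat.shape[1])
    dense = np.asarray(mat.todense())
    return 1.0 - np.prod(1.0 - dense, axis=0)


def compute_disconnectome(
    lesion: Volume,
    priors: ConnectivityPriors,
    method: str = "max",
) -> DisconnectomeMap:
    """Probability map of disconnection by a lesion.

    For each voxel v, P_Disco(v) = max over lesion voxels l of prior(v, l),
    treating the WM-by-GM priors table symmetrically (a lesioned WM voxel
    disconnects the GM voxels it connects to, and vice versa).  Voxels inside
    the lesion get P = 1.  ``method="union"`` replaces the max with the
    probabilistic union 1 - prod(1 - p); the union densifies the lesion's
    rows/columns, which is fine at phantom scale.
    """
    assert_same_grid(lesion, priors)
    les = lesion.values.astype(bool)
    if not les.any():
        raise ValueError("lesion mask is empty")
    if method not in {"max", "union"}:
        raise ValueError(f"unknown aggregation method {method!r}")
    agg = _sparse_col_max if method == "max" else _sparse_col_union

    les_lin = np.flatnonzero(les.ravel())
    p = np.zeros(priors.grid.n_voxels)

    wm_in = np.isin(priors.wm_voxels, les_lin)
    gm_in = np.isin(priors.gm_voxels, les_lin)
    if wm_in.any():  # lesioned WM rows -> GM columns
        p[priors.gm_voxels] = np.maximum(
            p[priors.gm_voxels], agg(priors.matrix[wm_in, :])
        )
    if gm_in.any():  # lesioned GM columns -> WM rows
        p[priors.wm_voxels] = np.maximum(
            p[priors.wm_voxels], agg(priors.matrix[:, gm_in].T)
        )
    if not wm_in.any() and not gm_in.any():
        logger.warning("lesion lies entirely outside the priors' coverage")
    p[les_lin] = 1.0
    return Volume(priors.grid, p.reshape(priors.grid.shape))


def discrover(
    rsn: RSNMapPair,
    disco: DisconnectomeMap,
    z_thr: float = DEFAULT_Z_THR,
) -> float:
    """DiscROver score in [0, 100] for one network.

    Membership is the strict suprathreshold support of the network's
    white-matter z-map; each member voxel is weighted by its raw z value.
    The score is invariant to positive rescaling of the z-map.
    """
    assert_same_grid(rsn.wm_zmap, disco)
    z = np.asarray(rsn.wm_zmap.values, dtype=float)
    member = z > z_thr
    if not member.any():
        raise ValueError(
            f"RSN {rsn.rsn_id}: no white-matter voxel exceeds z_thr={z_thr}"
        )
    zm = z[member]
    pm = np.asarray(disco.values, dtype=float)[member]
    return float(100.0 * np.sum(zm * pm) / np.sum(zm))


def presence_scores(
    roi: Volume,
    atlas: list[RSNMapPair],
    compartment: str = "wm",
    z_thr: float = DEFAULT_Z_THR,
) -> pd.DataFrame:
    """Presence of each network within a region of interest.

    raw(RSN) = sum of suprathreshold z values of the chosen compartment map
    inside the ROI; percent(RSN) normalises raw across networks to sum to
    100 (all zero, with a warning, if no network reaches into the ROI).
    """
    roi_mask = roi.values.astype(bool)
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    rows = []
    for rsn in atlas:
        zmap = rsn.zmap(compartment)
        assert_same_grid(zmap, roi)
        z = np.asarray(zmap.values, dtype=float)
        sel = roi_mask & (z > z_thr)
        rows.append((rsn.rsn_id, rsn.label, float(z[sel].sum())))
    df = pd.DataFrame(rows, columns=["rsn_id", "label", "raw_presence"])
    total = df["raw_presence"].sum()
    if total > 0:
        df["percent_presence"] = 100.0 * df["raw_presence"] / total
    else:
        logger.warning("no RSN present in the ROI above z_thr=%g", z_thr)
        df["percent_presence"] = 0.0
    return df


def score_report(
    lesion: Volume,
    atlas: list[RSNMapPair],
    priors: ConnectivityPriors,
    z_thr: float = DEFAULT_Z_THR,
    method: str = "max",
) -> pd.DataFrame:
    """DiscROver for every atlas network, sorted by score (desc, id asc)."""
    disco = compute_disconnectome(lesion, priors, method=method)
    rows = [
        (rsn.rsn_id, rsn.label, discrover(rsn, disco, z_thr=z_thr)) for rsn in atlas
    ]
    df = pd.DataFrame(rows, columns=["rsn_id", "label", "discrover"])
    return df.sort_values(
        ["discrover", "rsn_id"], ascending=[False, True], ignore_index=True
    )
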