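"""Overlap and coverage statistics over a set of RSN map pairs.

An atlas is a list of :class:`RSNMapPair` (paired grey- and white-matter
z-maps on a shared grid).  Maps are thresholded with a *strict* inequality
(z > thr, default 7), binarized and summed to count how many networks claim
each voxel; the module then reports coverage fractions and the distribution
of voxel sharing across networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volumes import Volume, assert_same_grid

__all__ = [
    "RSNMapPair",
    "threshold_binarize",
    "overlap_count",
    "coverage_fraction",
    "sharing_distribution",
    "pathway_profile",
    "DEFAULT_Z_THR",
]

#: Conservative atlas threshold: a voxel belongs to an RSN iff z > 7.
DEFAULT_Z_THR = 7.0


@dataclass
class RSNMapPair:
    """Paired grey- and white-matter z-maps for one resting-state network."""

    rsn_id: int
    gm_zmap: Volume
    wm_zmap: Volume
    label: str = ""

    def __post_init__(self) -> None:
        assert_same_grid(self.gm_zmap, self.wm_zmap)

    def zmap(self, compartment: str) -> Volume:
        if compartment == "gm":
            return self.gm_zmap
        if compartment == "wm":
            return self.wm_zmap
        raise ValueError(f"compartment must be 'gm' or 'wm', got {compartment!r}")


def threshold_binarize(zmap: Volume, z_thr: float = DEFAULT_Z_THR) -> Volume:
    """Binary support of a z-map: voxel true iff z > z_thr (strict)."""
    if not np.isfinite(z_thr):
        if z_thr == -np.inf:
            return Volume(zmap.grid, np.ones(zmap.grid.shape, dtype=bool))
        raise ValueError("z_thr must be finite or -inf")
    return Volume(zmap.grid, np.asarray(zmap.values) > z_thr)


def overlap_count(maps: list[Volume], z_thr: float = DEFAULT_Z_THR) -> Volume:
    """Per-voxel count of maps whose z exceeds the threshold.

    Conservation holds exactly: the summed overlap equals the sum of the
    individual binarized support sizes.
    """
    if not maps:
        raise ValueError("need at least one map")
    for m in maps[1:]:
        assert_same_grid(maps[0], m)
    count = np.zeros(maps[0].grid.shape, dtype=np.int64)
    for m in maps:
        count += threshold_binarize(m, z_thr).values
    return Volume(maps[0].grid, count)


def coverage_fraction(
    maps: list[Volume], tissue_mask: Volume, z_thr: float = DEFAULT_Z_THR
) -> float:
    """Fraction of the tissue mask covered by the union of binarized maps."""
    mask = tissue_mask.values.astype(bool)
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise ValueError("tissue mask is empty")
    count = overlap_count(maps, z_thr)
    assert_same_grid(count, tissue_mask)
    return float(((count.values > 0) & mask).sum() / n_mask)


def sharing_distribution(overlap: Volume, tissue_mask: Volume) -> pd.DataFrame:
    """Distribution of RSN-per-voxel counts within a tissue mask.

    Returns a table with one row per count value k (0, 1, 2, ...), the
    fraction of mask voxels at exactly k, and the cumulative fraction at
    >= k.  Fractions sum to 1 over rows.
    """
    assert_same_grid(overlap, tissue_mask)
    mask = tissue_mask.values.astype(bool)
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise ValueError("tissue mask is empty")
    vals = np.asarray(overlap.values)[mask].astype(np.int64)
    kmax = int(vals.max()) if vals.size else 0
    counts = np.bincount(vals, minlength=kmax + 1)
    frac = counts / n_mask
    cum = frac[::-1].cumsum()[::-1]  # fraction at >= k
    return pd.DataFrame({"k": np.arange(kmax + 1), "fraction": frac, "fraction_ge_k": cum})


def pathway_profile(overlap: Volume, roi_mask: Volume) -> dict[str, float]:
    """Boxplot-style summary of overlap counts within an ROI.

    Quartiles use linear interpolation (numpy's default, type-7); whiskers
    extend to the most extreme data points within 1.5 IQR of the quartile.
    """
    assert_same_grid(overlap, roi_mask)
    roi = roi_mask.values.astype(bool)
    if not roi.any():
        raise ValueError("ROI mask is empty")
    vals = np.asarray(overlap.values)[roi].astype(float)
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
    return {
        "n": float(vals.size),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(iqr),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "mean": float(vals.mean()),
    }
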