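"""Functionnectome projection: carry grey-matter BOLD into white matter.

The signal of a white-matter voxel is the combination of the BOLD signals of
the grey-matter voxels structurally connected to it, weighted by the
probability of connection given by anatomical priors.  The combination is a
weighted *mean* (division by the total weight), which keeps the projected
signal on the grey-matter signal scale and makes every output sample a convex
combination of its inputs.

Also provides the light temporal preprocessing used upstream of the
projection (per-voxel linear detrend, zero-phase Butterworth band-pass,
optional mask-restricted Gaussian smoothing).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.ndimage
import scipy.signal
import scipy.sparse as sp

from .volumes import FunctionalSeries, VoxelGrid, Volume, assert_same_grid

__all__ = [
    "ConnectivityPriors",
    "project_functionnectome",
    "preprocess_series",
    "bandpass",
    "save_priors",
    "load_priors",
]

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class ConnectivityPriors:
    """Sparse voxel-to-voxel probabilities of structural connection.

    ``matrix[i, j]`` is the probability that WM voxel ``wm_voxels[i]`` is
    structurally connected to GM voxel ``gm_voxels[j]``.  Voxel identifiers
    are linear (C-order) indices into the grid; absent entries mean 0 and
    stored entries lie in (0, 1].
    """

    grid: VoxelGrid
    wm_voxels: np.ndarray  # (n_wm,) linear indices
    gm_voxels: np.ndarray  # (n_gm,) linear indices
    matrix: sp.csr_matrix  # (n_wm, n_gm)

    def __post_init__(self) -> None:
        self.wm_voxels = np.asarray(self.wm_voxels, dtype=np.int64)
        self.gm_voxels = np.asarray(self.gm_voxels, dtype=np.int64)
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.shape != (len(self.wm_voxels), len(self.gm_voxels)):
            raise ValueError("priors matrix shape does not match voxel index tables")
        if self.matrix.nnz:
            d = self.matrix.data
            if d.min() <= 0 or d.max() > 1:
                raise ValueError("stored connection probabilities must lie in (0, 1]")

    @property
    def n_wm(self) -> int:
        return len(self.wm_voxels)

    @property
    def n_gm(self) -> int:
        return len(self.gm_voxels)

    def wm_mask(self) -> Volume:
        m = np.zeros(self.grid.n_voxels, dtype=bool)
        m[self.wm_voxels] = True
        return Volume(self.grid, m.reshape(self.grid.shape))

    def gm_mask(self) -> Volume:
        m = np.zeros(self.grid.n_voxels, dtype=bool)
        m[self.gm_voxels] = True
        return Volume(self.grid, m.reshape(self.grid.shape))


def project_functionnectome(
    series: FunctionalSeries,
    gm_mask: Volume,
    priors: ConnectivityPriors,
) -> FunctionalSeries:
    """Project a grey-matter BOLD series onto white matter voxels.

    For WM voxel ``v`` with weights ``w_g = prior(v, g)`` over GM voxels,

        out(v, t) = sum_g w_g * series(g, t) / sum_g w_g.

    WM voxels with zero total weight yield an all-zero time course (a warning
    reports their count).  The output shares the input grid, ``n_t`` and
    ``tr``; voxels outside the priors' WM set are zero.
    """
    assert_same_grid(series, gm_mask)
    assert_same_grid(series, priors)
    gm_lin = np.flatnonzero(gm_mask.values.astype(bool).ravel())
    if not np.isin(priors.gm_voxels, gm_lin).all():
        raise ValueError("priors reference GM voxels outside the grey-matter mask")

    flat = series.values.reshape(-1, series.n_t)
    sig_gm = flat[priors.gm_voxels]  # (n_gm, n_t)
    weight_sum = np.asarray(priors.matrix.sum(axis=1)).ravel()
    num = priors.matrix @ sig_gm  # (n_wm, n_t)
    covered = weight_sum > 0
    out_rows = np.zeros_like(num)
    out_rows[covered] = num[covered] / weight_sum[covered, None]
    n_uncovered = int((~covered).sum())
    if n_uncovered:
        logger.warning(
            "%d of %d WM voxels have no connectivity prior; their series are zero",
            n_uncovered,
            priors.n_wm,
        )
    out = np.zeros((series.grid.n_voxels, series.n_t))
    out[priors.wm_voxels] = out_rows
    return FunctionalSeries(
        series.grid, out.reshape(series.grid.shape + (series.n_t,)), tr=series.tr
    )


def bandpass(
    data: np.ndarray, low_hz: float, high_hz: float, tr: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    ``low_hz = 0`` degrades gracefully to a low-pass filter.
    """
    nyq = 0.5 / tr
    if not (0 <= low_hz < high_hz < nyq):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz violates 0 <= low < high < Nyquist ({nyq:.4g} Hz)"
        )
    if low_hz > 0:
        sos = scipy.signal.butter(order, [low_hz, high_hz], btype="band", fs=1.0 / tr, output="sos")
    else:
        sos = scipy.signal.butter(order, high_hz, btype="low", fs=1.0 / tr, output="sos")
    # default padding is far shorter than the impulse response at a 0.01 Hz
    # cutoff; pad by ~3 time constants (capped by the series length)
    # even-reflection padding sized to the slow edge of the band: the default
    # (short, odd) padding leaves visible edge transients at a 0.01 Hz cutoff
    edge_hz = low_hz if low_hz > 0 else high_hz
    padlen = min(np.asarray(data).shape[-1] - 1, int(3.0 / (edge_hz * tr)))
    return scipy.signal.sosfiltfilt(sos, data, axis=-1, padtype="even", padlen=padlen)


def preprocess_series(
    series: FunctionalSeries,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    detrend: bool = True,
    fwhm_mm: float | None = None,
    mask: Volume | None = None,
) -> FunctionalSeries:
    """Detrend, band-pass and optionally smooth a functional series.

    Smoothing is a Gaussian with sigma = fwhm / (2 sqrt(2 ln 2)) per axis (in
    voxels, from the grid's voxel size); when ``mask`` is given the kernel is
    renormalised inside the mask so signal does not bleed across its border.
    """
    data = series.values
    if mask is not None:
        assert_same_grid(series, mask)
    if detrend:
        data = scipy.signal.detrend(data, axis=-1, type="linear")
    data = bandpass(data, low_hz, high_hz, series.tr)
    if fwhm_mm is not None and fwhm_mm > 0:
        sigmas = [fwhm_mm * FWHM_TO_SIGMA / vs for vs in series.grid.voxel_size]
        m = mask.values.astype(bool) if mask is not None else np.ones(series.grid.shape, bool)
        norm = scipy.ndimage.gaussian_filter(m.astype(float), sigmas)
        out = np.zeros_like(data)
        for t in range(data.shape[-1]):
            sm = scipy.ndimage.gaussian_filter(data[..., t] * m, sigmas)
            out[..., t][m] = sm[m] / norm[m]
        data = out
    return FunctionalSeries(series.grid, np.ascontiguousarray(data), tr=series.tr)


# --------------------------------------------------------------------------
# Priors on disk: MatrixMarket + TSV index tables, or a single HDF5 container.

def save_priors(priors: ConnectivityPriors, path: str | Path) -> None:
    """Save priors to ``path``.

    ``*.h5`` writes a single HDF5 container; any other path is treated as a
    directory holding ``priors.mtx``, ``wm_voxels.tsv``, ``gm_voxels.tsv``
    and ``grid.json``.
    """
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        csr = priors.matrix.tocsr()
        with h5py.File(path, "w") as f:
            f.attrs["shape"] = priors.grid.shape
            f.attrs["affine"] = priors.grid.affine
            f.create_dataset("wm_voxels", data=priors.wm_voxels)
            f.create_dataset("gm_voxels", data=priors.gm_voxels)
            g = f.create_group("matrix")
            g.attrs["shape"] = csr.shape
            g.create_dataset("data", data=csr.data)
            g.create_dataset("indices", data=csr.indices)
            g.create_dataset("indptr", data=csr.indptr)
        return
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(path / "priors.mtx"), priors.matrix.tocoo())
    for name, lin in (("wm_voxels", priors.wm_voxels), ("gm_voxels", priors.gm_voxels)):
        i, j, k = np.unravel_index(lin, priors.grid.shape)
        pd.DataFrame({"linear_index": lin, "i": i, "j": j, "k": k}).to_csv(
            path / f"{name}.tsv", sep="\t", index=False
        )
    (path / "grid.json").write_text(
        json.dumps({"shape": list(priors.grid.shape), "affine": priors.grid.affine.tolist()})
    )


def load_priors(path: str | Path) -> ConnectivityPriors:
    """Load priors saved by :func:`save_priors` (format auto-detected)."""
    path = Path(path)
    if path.is_file() and path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            grid = VoxelGrid(tuple(int(s) for s in f.attrs["shape"]), np.array(f.attrs["affine"]))
            wm = f["wm_voxels"][()]
            gm = f["gm_voxels"][()]
            g = f["matrix"]
            mat = sp.csr_matrix(
                (g["data"][()], g["indices"][()], g["indptr"][()]),
                shape=tuple(int(s) for s in g.attrs["shape"]),
            )
        return ConnectivityPriors(grid, wm, gm, mat)
    if path.is_dir():
        meta = json.loads((path / "grid.json").read_text())
        grid = VoxelGrid(tuple(meta["shape"]), np.array(meta["affine"]))
        wm = pd.read_csv(path / "wm_voxels.tsv", sep="\t")["linear_index"].to_numpy()
        gm = pd.read_csv(path / "gm_voxels.tsv", sep="\t")["linear_index"].to_numpy()
        mat = sp.csr_matrix(scipy.io.mmread(str(path / "priors.mtx")))
        return ConnectivityPriors(grid, wm, gm, mat)
    raise ValueError(f"{path}: not a priors container (expected .h5 file or directory)")
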