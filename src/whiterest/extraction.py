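"""Spatial ICA on the concatenated GM+WM volume and cross-subject clustering.

Per subject, the grey-matter BOLD series and its white-matter projection are
spatially concatenated into one composite voxel set and decomposed by
spatial ICA (FastICA maximising the non-Gaussianity of the *spatial* maps);
the model order is chosen per subject by a Laplace (Minka) approximation of
the probabilistic-PCA evidence on the temporal covariance spectrum.  Each
independent component is z-scored over the composite mask, then split into a
paired grey-matter map and white-matter map.

Components are grouped across subjects by greedy centroid agglomeration on
the Pearson correlation of their grey-matter maps — at most one component
per subject per group — and each group is summarised by a voxelwise
one-sample t statistic converted to a z-map.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .atlas import RSNMapPair
from .phantom import GroundTruth
from .volumes import FunctionalSeries, VoxelGrid, Volume, assert_same_grid

__all__ = [
    "CompositeSeries",
    "ICPair",
    "RSNGroup",
    "IcaConvergenceError",
    "concat_spatial",
    "split_composite",
    "split_component",
    "estimate_order",
    "spatial_ica",
    "cluster_components",
    "group_zmap",
    "match_to_truth",
]

logger = logging.getLogger(__name__)

#: Normal-quantile overflow guard for degenerate (zero-variance) voxels.
Z_CAP = 38.0


class IcaConvergenceError(RuntimeError):
    """FastICA failed to converge, including after the seeded retry."""


@dataclass
class CompositeSeries:
    """Series over the disjoint union of the GM and WM voxel sets.

    ``data`` is (n_voxels, n_t) with GM voxels first; ``voxel_idx`` holds
    linear grid indices and ``compartment`` is 0 for GM, 1 for WM.
    """

    grid: VoxelGrid
    data: np.ndarray
    voxel_idx: np.ndarray
    compartment: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        if len(self.voxel_idx) != self.data.shape[0] or len(self.compartment) != self.data.shape[0]:
            raise ValueError("voxel bookkeeping does not match the data matrix")
        if len(np.unique(self.voxel_idx)) != len(self.voxel_idx):
            raise ValueError("compartments must partition the voxel set (duplicate voxel)")

    @property
    def n_t(self) -> int:
        return int(self.data.shape[1])

    @property
    def n_voxels(self) -> int:
        return int(self.data.shape[0])


@dataclass
class ICPair:
    """One independent component split into paired GM and WM z-maps."""

    subject: str
    component: int
    gm_zmap: Volume
    wm_zmap: Volume
    timecourse: np.ndarray


@dataclass
class RSNGroup:
    """A cross-subject group of matching components (<= 1 per subject)."""

    members: list[ICPair]
    n_subjects: int
    gm_zmap: Volume | None = None
    wm_zmap: Volume | None = None
    seed_r: float = field(default=np.nan)

    def __post_init__(self) -> None:
        subs = [m.subject for m in self.members]
        if len(set(subs)) != len(subs):
            raise ValueError("a group may contain at most one component per subject")

    @property
    def coverage(self) -> float:
        return len(self.members) / self.n_subjects


def concat_spatial(
    gm_series: FunctionalSeries,
    wm_series: FunctionalSeries,
    gm_mask: Volume,
    wm_mask: Volume,
) -> CompositeSeries:
    """Spatially concatenate a GM series with its WM projection."""
    assert_same_grid(gm_series, wm_series)
    assert_same_grid(gm_series, gm_mask)
    assert_same_grid(gm_series, wm_mask)
    if gm_series.n_t != wm_series.n_t:
        raise ValueError(f"frame count mismatch: {gm_series.n_t} vs {wm_series.n_t}")
    if abs(gm_series.tr - wm_series.tr) > 1e-9:
        raise ValueError(f"tr mismatch: {gm_series.tr} vs {wm_series.tr}")
    gm_lin = np.flatnonzero(gm_mask.values.astype(bool).ravel())
    wm_lin = np.flatnonzero(wm_mask.values.astype(bool).ravel())
    if np.intersect1d(gm_lin, wm_lin).size:
        raise ValueError("GM and WM masks overlap; compartments must be disjoint")
    flat_gm = gm_series.values.reshape(-1, gm_series.n_t)
    flat_wm = wm_series.values.reshape(-1, wm_series.n_t)
    data = np.vstack([flat_gm[gm_lin], flat_wm[wm_lin]])
    comp = np.concatenate([np.zeros(len(gm_lin), np.int8), np.ones(len(wm_lin), np.int8)])
    return CompositeSeries(
        grid=gm_series.grid,
        data=data,
        voxel_idx=np.concatenate([gm_lin, wm_lin]),
        compartment=comp,
        tr=gm_series.tr,
    )


def split_composite(comp: CompositeSeries) -> tuple[FunctionalSeries, FunctionalSeries]:
    """Invert :func:`concat_spatial` (zeros outside each compartment mask)."""
    out = []
    for c in (0, 1):
        sel = comp.compartment == c
        dense = np.zeros((comp.grid.n_voxels, comp.n_t))
        dense[comp.voxel_idx[sel]] = comp.data[sel]
        out.append(
            FunctionalSeries(comp.grid, dense.reshape(comp.grid.shape + (comp.n_t,)), tr=comp.tr)
        )
    return out[0], out[1]


def split_component(ic_map: np.ndarray, comp: CompositeSeries) -> tuple[Volume, Volume]:
    """Restrict a composite-space map to each compartment as a 3D volume."""
    ic_map = np.asarray(ic_map, dtype=float)
    if ic_map.shape != (comp.n_voxels,):
        raise ValueError(f"map length {ic_map.shape} != composite voxel count {comp.n_voxels}")
    vols = []
    for c in (0, 1):
        sel = comp.compartment == c
        dense = np.zeros(comp.grid.n_voxels)
        dense[comp.voxel_idx[sel]] = ic_map[sel]
        vols.append(Volume(comp.grid, dense.reshape(comp.grid.shape)))
    return vols[0], vols[1]


# --------------------------------------------------------------------------
# Model order: Laplace (Minka) evidence for probabilistic PCA.

def _minka_log_evidence(lam: np.ndarray, k: int, n: int) -> float:
    """Laplace-approximated log evidence of a k-component PPCA model.

    ``lam`` are the eigenvalues (descending) of the d x d sample covariance
    over n samples.  Returns -inf when the model is not identifiable at k
    (degenerate spectrum).
    """
    d = len(lam)
    if not 1 <= k < d:
        return -np.inf
    sigma2 = lam[k:].mean()
    if sigma2 <= 0 or lam[k - 1] <= 0:
        return -np.inf
    i = np.arange(1, k + 1)
    log_pu = -k * np.log(2.0) + np.sum(
        gammaln((d - i + 1) / 2.0) - ((d - i + 1) / 2.0) * np.log(np.pi)
    )
    log_lik = -n / 2.0 * np.sum(np.log(lam[:k])) - n * (d - k) / 2.0 * np.log(sigma2)
    m = d * k - k * (k + 1) // 2
    lam_hat = np.concatenate([lam[:k], np.full(d - k, sigma2)])
    log_az = 0.0
    for a in range(k):
        terms = (1.0 / lam_hat[a + 1:] - 1.0 / lam_hat[a]) * (lam[a] - lam[a + 1:]) * n
        if np.any(terms <= 0):
            return -np.inf
        log_az += np.sum(np.log(terms))
    return (
        log_pu
        + log_lik
        + (m + k) / 2.0 * np.log(2.0 * np.pi)
        - log_az / 2.0
        - k / 2.0 * np.log(n)
    )


def estimate_order(series: CompositeSeries, k_max: int) -> int:
    """Model order by Laplace-approximated PPCA evidence (always >= 1).

    Eigen-decomposes the time-by-time covariance (voxels as samples) and
    returns the k <= k_max with the highest evidence.  Data of exact low
    rank r (zero residual variance, where the evidence diverges) return
    min(r, k_max) directly.
    """
    n_all, d = series.data.shape
    if not 1 <= k_max < min(n_all, d):
        raise ValueError(f"k_max must satisfy 1 <= k_max < min(n_voxels, n_t) = {min(n_all, d)}")
    # Flat (zero-variance) voxels — e.g. prior-uncovered white matter — carry
    # no information; keeping them would overstate the sample count and make
    # the noise bulk look wider than the isotropic model predicts.
    live = series.data.std(axis=1) > 0
    n = int(live.sum())
    if n < 2:
        raise ValueError("degenerate (constant) data: no voxel has temporal variance")
    # Demean over *time* per voxel (not over voxels: subtracting the mean map
    # would remove a direction inside the signal subspace).
    x = series.data[live] - series.data[live].mean(axis=1, keepdims=True)
    cov = (x.T @ x) / n
    lam = np.linalg.eigvalsh(cov)[::-1]
    lam = np.clip(lam, 0.0, None)
    if lam[0] <= 0:
        raise ValueError("degenerate (constant) data: covariance spectrum is zero")
    tol = lam[0] * 1e-9
    rank = int((lam > tol).sum())
    if rank <= k_max:
        return rank  # exact low-rank data: evidence unbounded at k = rank
    # Restrict to the positive part of the spectrum: structurally dependent
    # voxels (e.g. a projection of other voxels) create exact zeros that
    # would bias the isotropic-noise estimate.
    lam = lam[:rank]
    ev = np.array([_minka_log_evidence(lam, k, n) for k in range(1, k_max + 1)])
    if not np.isfinite(ev).any():
        return 1
    return int(np.argmax(ev)) + 1


# --------------------------------------------------------------------------
# Spatial ICA.

def _run_fastica(data: np.ndarray, k: int, seed: int, max_iter: int, tol: float):
    """Whiten to k dimensions and run fixed-point ICA on the spatial maps.

    Whitening is done by hand on the temporal covariance of time-demeaned
    voxels: letting FastICA whiten would demean each time point over voxels,
    i.e. subtract the mean map, which lies inside the signal subspace and can
    silently absorb one source.
    """
    x = data - data.mean(axis=1, keepdims=True)
    n = x.shape[0]
    cov = (x.T @ x) / n
    lam, vec = np.linalg.eigh(cov)
    lam, vec = lam[::-1], vec[:, ::-1]
    if lam[k - 1] <= lam[0] * 1e-12:
        raise ValueError(f"data rank below requested k={k}")
    y = x @ vec[:, :k] / np.sqrt(lam[:k])  # (n_vox, k), unit voxel variance
    y -= y.mean(axis=0, keepdims=True)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        ica = FastICA(
            n_components=k,
            whiten=False,
            fun="logcosh",
            max_iter=max_iter,
            tol=tol,
            random_state=seed,
        )
        sources = ica.fit_transform(y)
    converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    # time courses: least-squares fit of the sources to the voxel data
    mixing, *_ = np.linalg.lstsq(sources, x, rcond=None)
    return sources, mixing.T, converged


def spatial_ica(
    series: CompositeSeries,
    k: int,
    seed: int,
    subject: str = "s0",
    max_iter: int = 1000,
    tol: float = 1e-5,
) -> list[ICPair]:
    """Extract k independent spatial components from a composite series.

    The data matrix (voxels x time) is whitened to k dimensions and
    decomposed by fixed-point ICA so the recovered *spatial* maps are
    maximally non-Gaussian.  Each map is z-scored over the composite mask,
    sign-oriented so its skewness is >= 0, and split into GM/WM volumes.
    Deterministic given the seed; non-convergence triggers one retry with a
    derived seed, then raises :class:`IcaConvergenceError`.
    """
    if not 1 <= k <= series.n_t:
        raise ValueError(f"k must be in [1, n_t={series.n_t}], got {k}")
    sources, mixing, converged = _run_fastica(series.data, k, seed, max_iter, tol)
    if not converged:
        retry_seed = (seed + 1000003) % (2**31)
        logger.warning("FastICA did not converge (seed=%d); retrying with seed=%d", seed, retry_seed)
        sources, mixing, converged = _run_fastica(series.data, k, retry_seed, max_iter, tol)
        if not converged:
            raise IcaConvergenceError(
                f"FastICA failed to converge after {max_iter} iterations (two seeds)"
            )
    # z-score over the live analysis mask only: flat voxels (e.g. WM without
    # prior coverage) carry no signal and must stay at exactly 0, not at the
    # negated mask mean.
    live = series.data.std(axis=1) > 0
    pairs = []
    for c in range(k):
        zmap = np.zeros(series.n_voxels)
        s = sources[live, c]
        zmap[live] = (s - s.mean()) / s.std()
        tc = mixing[:, c].copy()
        if scipy.stats.skew(zmap[live]) < 0:
            zmap, tc = -zmap, -tc
        gm_vol, wm_vol = split_component(zmap, series)
        pairs.append(ICPair(subject=subject, component=c, gm_zmap=gm_vol, wm_zmap=wm_vol, timecourse=tc))
    return pairs


# --------------------------------------------------------------------------
# Cross-subject clustering.

def _map_vectors(ics: list[ICPair], mask_lin: np.ndarray) -> np.ndarray:
    return np.stack([ic.gm_zmap.values.ravel()[mask_lin] for ic in ics])


def cluster_components(
    subjects: list[list[ICPair]],
    r_min: float = 0.4,
    coverage_min: float = 0.5,
    gm_mask: Volume | None = None,
) -> list[RSNGroup]:
    """Greedy centroid clustering of components across subjects.

    Repeatedly seeds a group with the highest-correlated unassigned pair of
    components from two different subjects (GM-map Pearson r >= r_min), then
    grows it: at each step the unassigned component (from a subject not yet
    in the group) best correlated with the current group centroid joins if
    r >= r_min, and the centroid is recomputed.  Groups keeping fewer than
    ``coverage_min`` of the subjects are discarded.  Order of subjects does
    not matter (up to exact correlation ties).
    """
    if len(subjects) < 2:
        raise ValueError("need components from at least 2 subjects")
    n_subjects = len(subjects)
    flat: list[ICPair] = [ic for subj in subjects for ic in subj]
    if not flat:
        raise ValueError("no components supplied")
    subj_of = np.array([s for s, subj in enumerate(subjects) for _ in subj])

    if gm_mask is not None:
        mask_lin = np.flatnonzero(gm_mask.values.astype(bool).ravel())
    else:
        union = np.zeros(flat[0].gm_zmap.grid.n_voxels, dtype=bool)
        for ic in flat:
            union |= ic.gm_zmap.values.ravel() != 0
        mask_lin = np.flatnonzero(union)
    vecs = _map_vectors(flat, mask_lin)
    zvecs = (vecs - vecs.mean(axis=1, keepdims=True))
    norms = np.linalg.norm(zvecs, axis=1)
    norms[norms == 0] = 1.0
    zvecs /= norms[:, None]
    corr = zvecs @ zvecs.T

    n = len(flat)
    unassigned = np.ones(n, dtype=bool)
    cross = subj_of[:, None] != subj_of[None, :]
    groups: list[RSNGroup] = []
    while True:
        avail = np.outer(unassigned, unassigned) & cross
        if not avail.any():
            break
        masked = np.where(avail, corr, -np.inf)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] < r_min:
            break
        member_idx = [int(i), int(j)]
        seed_r = float(masked[i, j])
        unassigned[i] = unassigned[j] = False
        while True:
            centroid = vecs[member_idx].mean(axis=0)
            c = centroid - centroid.mean()
            cn = np.linalg.norm(c)
            if cn == 0:
                break
            c /= cn
            r_to_centroid = zvecs @ c
            in_group_subjects = set(subj_of[member_idx])
            cand = unassigned & ~np.isin(subj_of, list(in_group_subjects))
            if not cand.any():
                break
            r_masked = np.where(cand, r_to_centroid, -np.inf)
            best = int(np.argmax(r_masked))
            if r_masked[best] < r_min:
                break
            member_idx.append(best)
            unassigned[best] = False
        members = sorted((flat[m] for m in member_idx), key=lambda ic: (ic.subject, ic.component))
        groups.append(RSNGroup(members=members, n_subjects=n_subjects, seed_r=seed_r))

    kept = [g for g in groups if g.coverage >= coverage_min]
    if not kept:
        logger.warning(
            "no component group survived (r_min=%.3g, coverage_min=%.3g); returning empty list",
            r_min,
            coverage_min,
        )
    return kept


def _t_to_z(tvals: np.ndarray, df: int) -> np.ndarray:
    """Map t statistics to normal quantiles, symmetric and overflow-safe."""
    z = np.zeros_like(tvals, dtype=float)
    pos = tvals >= 0
    with np.errstate(over="ignore"):
        z[pos] = scipy.stats.norm.isf(scipy.stats.t.sf(tvals[pos], df))
        z[~pos] = -scipy.stats.norm.isf(scipy.stats.t.sf(-tvals[~pos], df))
    return np.clip(z, -Z_CAP, Z_CAP)


def group_zmap(
    group: RSNGroup, rsn_id: int = 0, label: str = "", method: str = "stouffer"
) -> RSNMapPair:
    """Group z-map pair aggregated voxelwise across member z-maps.

    GM and WM compartments are aggregated separately.  ``method="stouffer"``
    (default) combines the member z-maps as sum(z)/sqrt(n) — the calibrated
    meta-analytic combination, whose null background stays N(0, 1) however
    consistent the members are.  ``method="t"`` computes the one-sample t
    statistic across members and maps it to a z-score through the t
    cumulative probability; note that for small groups this transform both
    saturates (t(7) caps practical z near 9) and inflates any tiny but
    consistent offset shared by the members.  Voxels where all members agree
    exactly map to 0 if the common value is 0, otherwise to the capped
    quantile +-38.
    """
    if len(group.members) < 2:
        raise ValueError("group z-map needs at least 2 members")
    if method not in {"stouffer", "t"}:
        raise ValueError(f"unknown aggregation method {method!r}")
    n = len(group.members)
    out = {}
    for compartment in ("gm", "wm"):
        stack = np.stack([getattr(m, f"{compartment}_zmap").values for m in group.members])
        if method == "stouffer":
            z = np.clip(stack.sum(axis=0) / np.sqrt(n), -Z_CAP, Z_CAP)
        else:
            mean = stack.mean(axis=0)
            sd = stack.std(axis=0, ddof=1)
            z = np.zeros_like(mean)
            ok = sd > 0
            t = np.zeros_like(mean)
            t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
            z[ok] = _t_to_z(t[ok], n - 1)
            degen = (~ok) & (mean != 0)
            z[degen] = np.sign(mean[degen]) * Z_CAP
        out[compartment] = Volume(group.members[0].gm_zmap.grid, z)
    pair = RSNMapPair(rsn_id=rsn_id, gm_zmap=out["gm"], wm_zmap=out["wm"], label=label)
    group.gm_zmap, group.wm_zmap = pair.gm_zmap, pair.wm_zmap
    return pair


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def match_to_truth(
    pairs: list[RSNMapPair], truth: GroundTruth
) -> list[dict]:
    """Optimal one-to-one assignment of recovered maps to planted networks.

    Maximises the summed GM spatial correlation (Hungarian algorithm) and
    reports per-match GM and WM correlations.  Extra recovered maps (or
    extra truths) are reported unmatched with ``truth_index = None``.
    """
    if not pairs:
        return []
    n_g, n_t = len(pairs), truth.n_networks
    gm_corr = np.zeros((n_g, n_t))
    wm_corr = np.zeros((n_g, n_t))
    for g, pair in enumerate(pairs):
        for t in range(n_t):
            gm_corr[g, t] = _safe_corr(
                pair.gm_zmap.values.ravel(), truth.gm_maps[t].values.ravel().astype(float)
            )
            wm_corr[g, t] = _safe_corr(
                pair.wm_zmap.values.ravel(), truth.wm_maps[t].values.ravel().astype(float)
            )
    rows, cols = linear_sum_assignment(-gm_corr)
    matched = dict(zip(rows.tolist(), cols.tolist()))
    report = []
    for g, pair in enumerate(pairs):
        if g in matched:
            t = matched[g]
            report.append(
                {
                    "group_index": g,
                    "rsn_id": pair.rsn_id,
                    "truth_index": t,
                    "gm_corr": float(gm_corr[g, t]),
                    "wm_corr": float(wm_corr[g, t]),
                }
            )
        else:
            report.append(
                {"group_index": g, "rsn_id": pair.rsn_id, "truth_index": None,
                 "gm_corr": np.nan, "wm_corr": np.nan}
            )
    return report
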