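"""Synthetic phantoms: anatomy, priors, resting-state series, lesions, cohorts.

The phantom emulates the data the real pipeline consumes, at desk scale:

* an anatomy of disjoint grey-matter "hubs" (spheres) connected, within each
  planted network, by straight white-matter "bundles";
* connectivity priors consistent with those bundles (each bundle voxel is
  connected to the grey matter of the two hubs it joins);
* resting-state BOLD in which each network's hubs share one band-limited
  (0.01-0.1 Hz) latent time course plus i.i.d. Gaussian noise;
* spherical lesions, and patient cohorts whose clinical scores are noisy
  linear functions of the true lesion-impact (DiscROver) values.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lesion import compute_disconnectome, discrover
from .projection import ConnectivityPriors, bandpass
from .volumes import FunctionalSeries, VoxelGrid, Volume

__all__ = [
    "PhantomSpec",
    "Anatomy",
    "GroundTruth",
    "PlacementError",
    "make_anatomy",
    "make_priors",
    "simulate_rest",
    "make_lesion",
    "simulate_cohort",
]

logger = logging.getLogger(__name__)


class PlacementError(RuntimeError):
    """Hub placement failed after bounded retries (grid too small)."""


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one synthetic subject.

    Defaults give the standard phantom used throughout the test bench: a 24^3
    grid carrying 3 networks of 2 hubs each, 300 frames at TR = 0.72 s and
    additive noise at half the (unit) network signal amplitude.
    """

    shape: tuple[int, int, int] = (24, 24, 24)
    n_networks: int = 3
    hubs_per_network: int = 3
    hub_radius: int = 2
    bundle_thickness: int = 1
    shell_thickness: float = 2.0
    noise_sd: float = 0.5
    n_t: int = 300
    tr: float = 0.72
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_networks < 1 or self.hubs_per_network < 1:
            raise ValueError("counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_t < 2:
            raise ValueError("n_t must be >= 2")

    @property
    def grid(self) -> VoxelGrid:
        return VoxelGrid.isotropic(self.shape)


@dataclass
class Anatomy:
    """Phantom anatomy: GM/WM masks plus the hub and bundle bookkeeping.

    ``hubs`` lists (network id, hub id, voxel linear indices); ``bundles``
    lists ((network id, hub id a, hub id b), voxel linear indices).  GM and
    WM masks are disjoint; their union is the phantom brain mask.
    """

    grid: VoxelGrid
    gm_mask: Volume
    wm_mask: Volume
    hubs: list[tuple[int, int, np.ndarray]]
    bundles: list[tuple[tuple[int, int, int], np.ndarray]]
    hub_centers: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    def brain_mask(self) -> Volume:
        return Volume(self.grid, self.gm_mask.values | self.wm_mask.values)

    def network_gm(self, net: int) -> np.ndarray:
        """Linear indices of the GM voxels of one network's hubs."""
        idx = [vox for n, _h, vox in self.hubs if n == net]
        return np.unique(np.concatenate(idx)) if idx else np.array([], dtype=np.int64)

    def network_wm(self, net: int) -> np.ndarray:
        idx = [vox for (n, _a, _b), vox in self.bundles if n == net]
        return np.unique(np.concatenate(idx)) if idx else np.array([], dtype=np.int64)


@dataclass
class GroundTruth:
    """Planted networks: per-network GM/WM membership maps + latent courses."""

    gm_maps: list[Volume]
    wm_maps: list[Volume]
    latents: np.ndarray  # (n_networks, n_t), unit variance each

    @property
    def n_networks(self) -> int:
        return len(self.gm_maps)


def _ball_offsets(radius: int) -> np.ndarray:
    r = int(radius)
    ax = np.arange(-r, r + 1)
    di, dj, dk = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = di**2 + dj**2 + dk**2 <= r**2
    return np.stack([di[keep], dj[keep], dk[keep]], axis=1)


def _sphere_lin(center: np.ndarray, radius: int, shape: tuple[int, int, int]) -> np.ndarray:
    pts = center[None, :] + _ball_offsets(radius)
    ok = np.all((pts >= 0) & (pts < np.array(shape)), axis=1)
    pts = pts[ok]
    return np.ravel_multi_index((pts[:, 0], pts[:, 1], pts[:, 2]), shape)


def _segment_voxels(a: np.ndarray, b: np.ndarray, shape, thickness: int) -> np.ndarray:
    """Voxels of the straight segment a-b dilated to the given tube radius."""
    n_steps = max(2, int(4 * np.linalg.norm(b - a)) + 1)
    t = np.linspace(0.0, 1.0, n_steps)[:, None]
    pts = np.round(a[None, :] * (1 - t) + b[None, :] * t).astype(int)
    lin = set()
    offs = _ball_offsets(thickness)
    for p in np.unique(pts, axis=0):
        q = p[None, :] + offs
        ok = np.all((q >= 0) & (q < np.array(shape)), axis=1)
        q = q[ok]
        lin.update(np.ravel_multi_index((q[:, 0], q[:, 1], q[:, 2]), shape).tolist())
    return np.array(sorted(lin), dtype=np.int64)


def make_anatomy(spec: PhantomSpec) -> Anatomy:
    """Build a spherical phantom brain with hubs, bundles, and a GM shell.

    The brain is a ball; its outermost ``shell_thickness`` voxels form a
    cortex-like grey-matter shell carrying background (non-network) signal.
    Hub spheres are placed inside the white-matter interior — so the straight
    bundles joining a network's hubs always run through white matter — and
    belong to the grey-matter mask together with the shell.  The rest of the
    interior is the white-matter mask; only bundle voxels receive
    connectivity, the remainder emulates prior-uncovered white matter.

    Deterministic given ``spec.seed``.  Raises :class:`PlacementError` if the
    grid cannot host all hubs without overlap after bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    shape = np.array(spec.shape)
    center = (shape - 1) / 2.0
    brain_r = shape.min() / 2.0 - 1.0
    shell_in = brain_r - spec.shell_thickness
    # Hub centers lie in the interior; the spheres may reach into the shell
    # (they are grey matter either way) but must stay inside the brain.
    hub_r_max = min(shell_in, brain_r - spec.hub_radius) - 0.5
    if hub_r_max < 0.5:
        raise PlacementError(
            f"grid {spec.shape} too small for hub radius {spec.hub_radius} "
            f"inside a shell of thickness {spec.shell_thickness}"
        )
    n_hubs = spec.n_networks * spec.hubs_per_network
    min_dist = 2 * spec.hub_radius + 2  # disjoint spheres with a 1-voxel gap

    ii, jj, kk = np.indices(spec.shape)
    dist = np.sqrt(
        (ii - center[0]) ** 2 + (jj - center[1]) ** 2 + (kk - center[2]) ** 2
    )
    brain = dist <= brain_r
    interior = dist <= shell_in
    shell = brain & ~interior
    cand = np.argwhere(dist <= hub_r_max)

    centers: list[np.ndarray] = []
    for _restart in range(50):
        centers = []
        ok = True
        for _ in range(n_hubs):
            placed = False
            for _attempt in range(500):
                c = cand[rng.integers(len(cand))]
                if all(np.linalg.norm(c - o) >= min_dist for o in centers):
                    centers.append(c)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            break
    else:
        raise PlacementError(
            f"could not place {n_hubs} hubs of radius {spec.hub_radius} on grid {spec.shape}"
        )

    hubs: list[tuple[int, int, np.ndarray]] = []
    hub_centers: dict[tuple[int, int], np.ndarray] = {}
    gm = shell.ravel().copy()
    i = 0
    for net in range(spec.n_networks):
        for hub in range(spec.hubs_per_network):
            lin = _sphere_lin(centers[i], spec.hub_radius, spec.shape)
            hubs.append((net, hub, lin))
            hub_centers[(net, hub)] = centers[i]
            gm[lin] = True
            i += 1

    wm = interior.ravel() & ~gm
    bundles: list[tuple[tuple[int, int, int], np.ndarray]] = []
    for net in range(spec.n_networks):
        for a, b in itertools.combinations(range(spec.hubs_per_network), 2):
            lin = _segment_voxels(
                hub_centers[(net, a)], hub_centers[(net, b)], spec.shape, spec.bundle_thickness
            )
            lin = lin[wm[lin]]  # bundles live strictly in white matter
            if lin.size == 0:
                raise PlacementError(f"bundle ({net},{a},{b}) is empty after GM exclusion")
            bundles.append(((net, a, b), lin))

    grid = spec.grid
    return Anatomy(
        grid=grid,
        gm_mask=Volume(grid, gm.reshape(spec.shape)),
        wm_mask=Volume(grid, wm.reshape(spec.shape)),
        hubs=hubs,
        bundles=bundles,
        hub_centers=hub_centers,
    )


def make_priors(anatomy: Anatomy, p_on: float = 1.0) -> ConnectivityPriors:
    """Connectivity priors consistent with the phantom's bundles.

    Every bundle voxel is connected with probability ``p_on`` to every GM
    voxel of the two hubs the bundle joins; all other entries are zero.  A
    voxel shared by crossing bundles is connected to all their endpoint hubs.
    """
    if not 0 < p_on <= 1:
        raise ValueError("p_on must be in (0, 1]")
    if not anatomy.bundles:
        raise ValueError("anatomy has no bundles")
    import scipy.sparse as sp

    wm_voxels = np.flatnonzero(anatomy.wm_mask.values.ravel())
    gm_voxels = np.flatnonzero(anatomy.gm_mask.values.ravel())
    wm_pos = {int(v): i for i, v in enumerate(wm_voxels)}
    gm_pos = {int(v): i for i, v in enumerate(gm_voxels)}
    hub_lin = {(n, h): vox for n, h, vox in anatomy.hubs}

    rows, cols = [], []
    for (net, a, b), bundle in anatomy.bundles:
        gm_targets = np.concatenate([hub_lin[(net, a)], hub_lin[(net, b)]])
        r = np.array([wm_pos[int(v)] for v in bundle])
        c = np.array([gm_pos[int(g)] for g in gm_targets])
        rr, cc = np.meshgrid(r, c, indexing="ij")
        rows.append(rr.ravel())
        cols.append(cc.ravel())
    pairs = np.unique(np.stack([np.concatenate(rows), np.concatenate(cols)]), axis=1)
    mat = sp.csr_matrix(
        (np.full(pairs.shape[1], p_on), (pairs[0], pairs[1])),
        shape=(len(wm_voxels), len(gm_voxels)),
    )
    return ConnectivityPriors(anatomy.grid, wm_voxels, gm_voxels, mat)


def simulate_rest(anatomy: Anatomy, spec: PhantomSpec) -> tuple[FunctionalSeries, GroundTruth]:
    """Simulate grey-matter resting-state BOLD with planted networks.

    Each network gets one latent time course: white noise band-passed to
    0.01-0.1 Hz at the spec's TR and standardised to unit variance.  A GM
    voxel's signal is the sum of the latents of the networks it belongs to
    plus i.i.d. Normal(0, noise_sd); voxels outside the GM mask are zero.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n_net = spec.n_networks
    latents = rng.standard_normal((n_net, spec.n_t))
    latents = bandpass(latents, 0.01, 0.1, spec.tr)  # raises on Nyquist violation
    latents = (latents - latents.mean(axis=1, keepdims=True)) / latents.std(
        axis=1, keepdims=True
    )

    n_vox = anatomy.grid.n_voxels
    data = np.zeros((n_vox, spec.n_t))
    gm_maps, wm_maps = [], []
    for net in range(n_net):
        gm_lin = anatomy.network_gm(net)
        wm_lin = anatomy.network_wm(net)
        data[gm_lin] += latents[net]
        g = np.zeros(n_vox, dtype=bool)
        g[gm_lin] = True
        w = np.zeros(n_vox, dtype=bool)
        w[wm_lin] = True
        gm_maps.append(Volume(anatomy.grid, g.reshape(anatomy.grid.shape)))
        wm_maps.append(Volume(anatomy.grid, w.reshape(anatomy.grid.shape)))

    gm_lin_all = np.flatnonzero(anatomy.gm_mask.values.ravel())
    if spec.noise_sd > 0:
        data[gm_lin_all] += rng.normal(0.0, spec.noise_sd, size=(len(gm_lin_all), spec.n_t))
    series = FunctionalSeries(
        anatomy.grid, data.reshape(anatomy.grid.shape + (spec.n_t,)), tr=spec.tr
    )
    return series, GroundTruth(gm_maps, wm_maps, latents)


def make_lesion(anatomy: Anatomy, center: tuple[int, int, int], radius: int) -> Volume:
    """Spherical lesion of the given voxel radius, clipped to the brain mask."""
    center = np.asarray(center, dtype=int)
    shape = anatomy.grid.shape
    if np.any(center < 0) or np.any(center >= np.array(shape)):
        raise ValueError(f"lesion center {tuple(center)} outside grid {shape}")
    lin = _sphere_lin(center, radius, shape)
    brain = anatomy.brain_mask().values.ravel()
    lin = lin[brain[lin]]
    if lin.size == 0:
        raise ValueError("lesion does not intersect the brain mask")
    mask = np.zeros(anatomy.grid.n_voxels, dtype=bool)
    mask[lin] = True
    return Volume(anatomy.grid, mask.reshape(shape))


def simulate_cohort(
    n_patients: int,
    atlas: list,
    priors: ConnectivityPriors,
    anatomy: Anatomy,
    slope: float = 1.0,
    noise_sd: float = 0.1,
    n_scores: int = 7,
    seed: int = 0,
    z_thr: float = 7.0,
    radius_range: tuple[int, int] = (1, 4),
    target_r: float | None = None,
) -> tuple[list[Volume], pd.DataFrame]:
    """Simulate a stroke cohort whose deficits track true DiscROver values.

    Each patient gets a random spherical lesion centred on a white-matter
    voxel.  For every atlas network j the latent deficit is

        d_ij = slope * DiscROver_ij / 100 + Normal(0, noise_sd)

    and each of the ``n_scores`` clinical columns for that deficit adds
    independent Normal(0, 0.1) measurement noise.  ``target_r`` overrides
    ``noise_sd`` by solving for the value that makes the latent deficit
    correlate with DiscROver at the requested level given the realised
    DiscROver spread.  Covariates (age, sex, chronicity) are drawn
    independently of everything else.  Deterministic given ``seed``.

    Returns the lesion masks and a table with one row per patient: true
    DiscROver and latent deficit per network, clinical score columns
    ``rsn{j}_score{k}``, and covariates.
    """
    if n_patients < 3:
        raise ValueError("need at least 3 patients")
    if n_scores < 1:
        raise ValueError("need at least 1 clinical score column")
    if not atlas:
        raise ValueError("atlas is empty")
    for rsn in atlas:
        if not (np.asarray(rsn.wm_zmap.values) > z_thr).any():
            raise ValueError(f"degenerate atlas: RSN {rsn.rsn_id} has no suprathreshold voxel")

    rng = np.random.default_rng(seed)
    wm_coords = np.argwhere(anatomy.wm_mask.values)
    lesions: list[Volume] = []
    centers, radii = [], []
    for _ in range(n_patients):
        c = wm_coords[rng.integers(len(wm_coords))]
        r = int(rng.integers(radius_range[0], radius_range[1] + 1))
        lesions.append(make_lesion(anatomy, tuple(c), r))
        centers.append(c)
        radii.append(r)

    n_rsn = len(atlas)
    D = np.zeros((n_patients, n_rsn))
    for i, les in enumerate(lesions):
        disco = compute_disconnectome(les, priors)
        for j, rsn in enumerate(atlas):
            D[i, j] = discrover(rsn, disco, z_thr=z_thr)

    table = {"patient_id": [f"p{i:03d}" for i in range(n_patients)]}
    table["lesion_radius"] = radii
    for ax, name in enumerate("ijk"):
        table[f"lesion_{name}"] = [int(c[ax]) for c in centers]

    for j in range(n_rsn):
        x = slope * D[:, j] / 100.0
        if target_r is not None:
            sx = float(np.std(x))
            if sx == 0:
                raise ValueError("DiscROver is constant across patients; cannot hit target_r")
            sd_j = sx * np.sqrt(1.0 / target_r**2 - 1.0)
        else:
            sd_j = noise_sd
        d = x + rng.normal(0.0, sd_j, size=n_patients)
        table[f"discrover_rsn{j}"] = D[:, j]
        table[f"deficit_rsn{j}"] = d
        for k in range(n_scores):
            table[f"rsn{j}_score{k}"] = d + rng.normal(0.0, 0.1, size=n_patients)

    table["age"] = np.clip(rng.normal(54, 11, n_patients), 19, 83)
    table["sex"] = rng.integers(0, 2, n_patients)
    table["chronicity"] = np.clip(rng.normal(13, 4.9, n_patients), 1, None)
    return lesions, pd.DataFrame(table)
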