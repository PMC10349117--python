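"""Shared phantom fixtures.

The expensive ones (default phantom, the eight-subject pipeline run) are
session-scoped so the recovery tests and the acceptance checks reuse a
single computation.
"""

import logging

import numpy as np
import pytest

import whiterest as wr

logging.getLogger("whiterest").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_spec() -> wr.PhantomSpec:
    return wr.PhantomSpec()


@pytest.fixture(scope="session")
def anatomy(default_spec) -> wr.Anatomy:
    return wr.make_anatomy(default_spec)


@pytest.fixture(scope="session")
def priors(anatomy) -> wr.ConnectivityPriors:
    return wr.make_priors(anatomy, p_on=1.0)


@pytest.fixture(scope="session")
def truth(anatomy, default_spec) -> wr.GroundTruth:
    _, t = wr.simulate_rest(anatomy, default_spec)
    return t


@pytest.fixture(scope="session")
def truth_atlas(anatomy, truth) -> list[wr.RSNMapPair]:
    """Atlas built from the planted maps, lifted above the z > 7 threshold."""
    return [
        wr.RSNMapPair(
            i,
            wr.Volume(anatomy.grid, truth.gm_maps[i].values * 10.0),
            wr.Volume(anatomy.grid, truth.wm_maps[i].values * 10.0),
            label=f"planted{i:02d}",
        )
        for i in range(truth.n_networks)
    ]


@pytest.fixture(scope="session")
def small_anatomy() -> wr.Anatomy:
    """16^3 phantom used for the projection-contract checks."""
    spec = wr.PhantomSpec(
        shape=(16, 16, 16), n_networks=2, hubs_per_network=2, hub_radius=1, n_t=40, seed=3
    )
    return wr.make_anatomy(spec)


@pytest.fixture(scope="session")
def pipeline_run(anatomy, priors, default_spec):
    """Full eight-subject extraction on the default phantom (fixed seeds).

    Returns (subjects' ICs, groups, group map pairs, truth-match report,
    ground truth).
    """
    subjects = []
    truth = None
    for s in range(8):
        spec = wr.PhantomSpec(seed=100 + s)
        series, truth = wr.simulate_rest(anatomy, spec)
        wm_series = wr.project_functionnectome(series, anatomy.gm_mask, priors)
        comp = wr.concat_spatial(series, wm_series, anatomy.gm_mask, anatomy.wm_mask)
        k = wr.estimate_order(comp, 30)
        subjects.append(wr.spatial_ica(comp, k, seed=s, subject=f"s{s}"))
    groups = wr.cluster_components(subjects, r_min=0.4, coverage_min=0.5, gm_mask=anatomy.gm_mask)
    pairs = [wr.group_zmap(g, rsn_id=i, label=f"rsn{i:02d}") for i, g in enumerate(groups)]
    report = wr.match_to_truth(pairs, truth)
    return subjects, groups, pairs, report, truth


@pytest.fixture(scope="session")
def cohort_study(anatomy, priors, truth_atlas):
    """Twenty simulated cohorts (n = 131) calibrated to a generative r of 0.7.

    Returns per-seed fitted correlations and bootstrap-band coverages of the
    true regression line.
    """
    rs, coverages = [], []
    for seed in range(20):
        _, tab = wr.simulate_cohort(
            131, truth_atlas, priors, anatomy, slope=1.0, target_r=0.7, seed=seed
        )
        x = tab["discrover_rsn0"].to_numpy()
        y = tab["deficit_rsn0"].to_numpy()
        rs.append(wr.fit_linear(x, y).r)
        band = wr.bootstrap_band(x, y, n_boot=1000, level=0.95, seed=seed + 1000)
        true_line = 1.0 * band["grid"] / 100.0  # generative slope 1.0, intercept 0
        coverages.append(
            float(((true_line >= band["low"]) & (true_line <= band["high"])).mean())
        )
    return np.array(rs), np.array(coverages)
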