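"""Shared fixtures: synthetic scenes rendered once per session.

The default scene is the four-concentration reference design (10^3, 10^2,
10, 1 cells/μl; six 1-μl droplets each on a 4 × 6 array, 30-min frames for
72 h).  The marine scene emulates the environmental-sample experiment:
36 droplets loaded at 0.25 cells per droplet with wide dormancy lags.
"""

import pytest

from moca import growth, imaging
from moca import scene as sc


@pytest.fixture(scope="session")
def default_scene():
    return sc.plan_experiment(
        sc.DropletLayout(), [1000.0, 100.0, 10.0, 1.0], 6, 1.0, seed=7
    )


@pytest.fixture(scope="session")
def default_render(default_scene):
    stack, truth = sc.render_stack(default_scene)
    return stack, truth


@pytest.fixture(scope="session")
def default_series(default_scene, default_render):
    stack, _ = default_render
    rois = imaging.locate_droplets(stack, default_scene.layout, mode="grid")
    return imaging.extract_transmission(stack, rois, default_scene.times_h)


@pytest.fixture(scope="session")
def default_results(default_scene, default_series):
    groups = {d.droplet_id: d.group for d in default_scene.droplets}
    return growth.analyze_experiment(default_series, groups)


@pytest.fixture(scope="session")
def marine_scene():
    layout = sc.DropletLayout(n_rows=6, n_cols=6)
    lag = sc.GrowthParams(lag_mean_h=6.0, lag_sd_h=4.0)
    return sc.plan_experiment(layout, [0.25], 36, 1.0, seed=42, growth=lag)


@pytest.fixture(scope="session")
def marine_render(marine_scene):
    stack, truth = sc.render_stack(marine_scene)
    return stack, truth


@pytest.fixture(scope="session")
def exponential_scene():
    """Noiseless, lag-free droplets with exactly 1, 10, 100, 1000 cells
    (effectively unlimited capacity): the closed-form exponential regime."""
    g = sc.GrowthParams(lag_mean_h=0.0, lag_sd_h=0.0, carrying_capacity=1e9)
    r = sc.RenderParams(noise_sd=0.0, illumination_low=1.0, illumination_high=1.0)
    layout = sc.DropletLayout(n_rows=1, n_cols=4)
    return sc.build_scene(
        layout,
        [1, 10, 100, 1000],
        [1, 10, 100, 1000],
        growth=g,
        render=r,
        times_h=sc.default_times(24.0, 0.5),
        seed=3,
    )


@pytest.fixture(scope="session")
def exponential_results(exponential_scene):
    stack, truth = sc.render_stack(exponential_scene)
    rois = imaging.locate_droplets(stack, exponential_scene.layout, mode="grid")
    series = imaging.extract_transmission(stack, rois, exponential_scene.times_h)
    groups = {d.droplet_id: d.group for d in exponential_scene.droplets}
    return growth.analyze_experiment(series, groups), truth
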