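"""Synthetic droplet-array cultivation experiments with ground truth.

A scene emulates an automated bright-field time-lapse of a plasma-patterned
droplet array: a grid of 1-μl droplets sitting on hydrophilic disks under
oil, imaged one field of view per droplet at a fixed cadence.  Each droplet
receives a Poisson number of founder cells; every founder grows into its own
microcolony after a cell-specific lag, the colonies share the droplet's
carrying capacity, and the rendered micrograph darkens as biomass
accumulates.  Optionally, a droplet brightens again after the population
peaks (sporulating cells shrink without dying), which reproduces the
post-peak transmission rebound seen in *Bacillus subtilis* cultures.

The generator is the ground-truth oracle for the extraction and analysis
modules: alongside the frame stack it emits, per droplet, the seeded cell
count, per-cell lags, colony positions, the latent-signal threshold-crossing
time, the population-plateau time, the colony merge time, and a "countable"
checkpoint frame at which microcolonies are large but not yet merged.

Optics are deliberately minimal: each colony is a disk whose area is
proportional to its biomass, attenuating transmitted light by a fixed
Beer–Lambert-style optical depth; constants are free parameters of the
generator, not claims about any particular instrument.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile

from . import occupancy
from ._disks import coverage_stamp, disk_coverage_patch, disk_mask, disk_overlap_area

__all__ = [
    "DropletLayout",
    "GrowthParams",
    "RenderParams",
    "DropletTruth",
    "SyntheticScene",
    "default_times",
    "plan_experiment",
    "build_scene",
    "simulate_biomass",
    "render_stack",
    "write_scene",
    "load_scene",
]

#: Colony area (px) above which a microcolony is considered countable in the
#: checkpoint-frame ground truth (10 × the segmentation min_area default).
COUNTABLE_COLONY_AREA_PX = 200.0


class ConfigurationError(ValueError):
    """Scene plan inconsistent with the array layout."""


def default_times(t_end_h: float = 72.0, interval_h: float = 0.5) -> np.ndarray:
    """Frame timestamps in hours: 0 to ``t_end_h`` every ``interval_h`` (default
    the 30-min cadence over 72 h, i.e. 145 frames)."""
    n = int(round(t_end_h / interval_h))
    return np.linspace(0.0, n * interval_h, n + 1)


@dataclass(frozen=True)
class DropletLayout:
    """Geometry of the hydrophilic spot array and of the per-droplet frame.

    Defaults follow the stencil used for the physical array: a 4 × 6 grid of
    3.18-mm hydrophilic disks, each holding a 1-μl droplet, imaged with one
    field of view per droplet.
    """

    n_rows: int = 4
    n_cols: int = 6
    spot_diameter_mm: float = 3.18
    pitch_mm: float = 4.5
    pixels_per_mm: float = 100.0
    frame_margin: float = 0.2  # extra frame half-width, fraction of spot radius

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("layout must contain at least one droplet")
        if self.spot_diameter_mm <= 0:
            raise ValueError("spot_diameter_mm must be > 0")
        if self.pitch_mm < self.spot_diameter_mm:
            raise ValueError("pitch_mm must be >= spot_diameter_mm")
        if self.pixels_per_mm <= 0:
            raise ValueError("pixels_per_mm must be > 0")

    @property
    def n_droplets(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def spot_radius_px(self) -> float:
        return 0.5 * self.spot_diameter_mm * self.pixels_per_mm

    @property
    def frame_shape(self) -> tuple[int, int]:
        """Frame side chosen (odd) so one frame covers one droplet with margin."""
        half = int(math.ceil(self.spot_radius_px * (1.0 + self.frame_margin)))
        side = 2 * half + 1
        return (side, side)

    @property
    def frame_center(self) -> tuple[float, float]:
        side = self.frame_shape[0]
        c = (side - 1) / 2.0
        return (c, c)

    def droplet_id(self, row: int, col: int) -> int:
        return row * self.n_cols + col

    def position(self, droplet_id: int) -> tuple[int, int]:
        return divmod(droplet_id, self.n_cols)


@dataclass
class GrowthParams:
    """Latent per-droplet growth process.

    Each founder cell starts a colony of biomass ``initial_biomass_per_cell``
    that stays dormant until its lag ends, then grows at specific rate μ
    under a shared logistic brake: db_i/dt = μ b_i (1 − Σ_j b_j / K).
    Biomass is in nominal cell units, so ``carrying_capacity`` is roughly the
    cell count of a saturated droplet.  With ``sporulation`` set, once the
    population reaches 99% of K the counts freeze and the colonies' optical
    attenuation relaxes linearly to (1 − rebound_fraction) of its peak over
    ``rebound_ramp_h`` hours — cells shrink, the droplet brightens.
    """

    specific_growth_rate: float = 0.7  # per hour (doubling time ~1 h)
    lag_mean_h: float = 2.0
    lag_sd_h: float = 1.0
    initial_biomass_per_cell: float = 1.0
    carrying_capacity: float = 1.5e6
    sporulation: bool = False
    rebound_ramp_h: float = 6.0
    rebound_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.specific_growth_rate <= 0:
            raise ValueError("specific_growth_rate must be > 0")
        if self.lag_mean_h < 0 or self.lag_sd_h < 0:
            raise ValueError("lag parameters must be >= 0")
        if self.initial_biomass_per_cell <= 0:
            raise ValueError("initial_biomass_per_cell must be > 0")
        if self.carrying_capacity <= self.initial_biomass_per_cell:
            raise ValueError("carrying_capacity must exceed initial_biomass_per_cell")
        if not 0.0 <= self.rebound_fraction <= 1.0:
            raise ValueError("rebound_fraction must be in [0, 1]")
        if self.rebound_ramp_h <= 0:
            raise ValueError("rebound_ramp_h must be > 0")


@dataclass
class RenderParams:
    """Optical rendering constants (free parameters of the generator)."""

    background_intensity: float = 200.0  # 8-bit gray of an empty droplet
    oil_intensity: float = 120.0  # outside-spot (oil) gray level
    colony_optical_depth: float = 2.5  # Beer-Lambert depth of colony interior
    colony_area_per_biomass: float = 0.03  # px^2 per biomass unit
    noise_sd: float = 2.0  # additive Gaussian camera noise, gray levels
    illumination_low: float = 0.9  # per-droplet illumination multiplier range
    illumination_high: float = 1.1
    measurement_shrink: float = 0.9  # fraction of spot radius used for means
    placement_radius_fraction: float = 0.8  # colony centers within this Rspot

    def __post_init__(self) -> None:
        if self.colony_optical_depth <= 0 or self.colony_area_per_biomass <= 0:
            raise ValueError("optical depth and area-per-biomass must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.measurement_shrink <= 1:
            raise ValueError("measurement_shrink must be in (0, 1]")
        if not 0 < self.placement_radius_fraction < 1:
            raise ValueError("placement_radius_fraction must be in (0, 1)")


@dataclass
class DropletTruth:
    """Per-droplet ground truth fixed at scene-build time."""

    droplet_id: int
    row: int
    col: int
    group: float  # nominal cells per droplet (concentration x volume)
    cell_count: int
    lags_h: np.ndarray  # (cell_count,) hours
    centers_px: np.ndarray  # (cell_count, 2) (row, col) within the frame
    illumination: float


@dataclass
class SyntheticScene:
    """A fully specified synthetic experiment (ground truth + render recipe)."""

    layout: DropletLayout
    times_h: np.ndarray
    growth: GrowthParams
    render: RenderParams
    droplets: list[DropletTruth]
    seed: int
    substep_h: float = 0.05

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("times_h must be a strictly increasing 1-D array")
        self.times_h = t
        if self.substep_h <= 0:
            raise ValueError("substep_h must be > 0")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "layout": dataclasses.asdict(self.layout),
            "times_h": self.times_h.tolist(),
            "growth": dataclasses.asdict(self.growth),
            "render": dataclasses.asdict(self.render),
            "seed": self.seed,
            "substep_h": self.substep_h,
            "rng": "numpy PCG64 (default_rng)",
            "droplets": [
                {
                    "droplet_id": d.droplet_id,
                    "row": d.row,
                    "col": d.col,
                    "group": d.group,
                    "cell_count": d.cell_count,
                    "lags_h": np.asarray(d.lags_h).tolist(),
                    "centers_px": np.asarray(d.centers_px).reshape(-1, 2).tolist(),
                    "illumination": d.illumination,
                }
                for d in self.droplets
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticScene":
        droplets = [
            DropletTruth(
                droplet_id=d["droplet_id"],
                row=d["row"],
                col=d["col"],
                group=d["group"],
                cell_count=d["cell_count"],
                lags_h=np.asarray(d["lags_h"], dtype=float),
                centers_px=np.asarray(d["centers_px"], dtype=float).reshape(-1, 2),
                illumination=d["illumination"],
            )
            for d in data["droplets"]
        ]
        return cls(
            layout=DropletLayout(**data["layout"]),
            times_h=np.asarray(data["times_h"], dtype=float),
            growth=GrowthParams(**data["growth"]),
            render=RenderParams(**data["render"]),
            droplets=droplets,
            seed=data["seed"],
            substep_h=data.get("substep_h", 0.05),
        )


# ---------------------------------------------------------------------------
# scene construction
# ---------------------------------------------------------------------------


def _sample_lags(rng: np.random.Generator, n: int, growth: GrowthParams) -> np.ndarray:
    """Per-cell lags, lognormal with the requested arithmetic mean and sd."""
    if n == 0:
        return np.zeros(0)
    m, s = growth.lag_mean_h, growth.lag_sd_h
    if m == 0:
        return np.zeros(n)
    if s == 0:
        return np.full(n, m)
    sigma2 = math.log(1.0 + (s / m) ** 2)
    mu = math.log(m) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)


def _place_colonies(
    rng: np.random.Generator,
    n: int,
    layout: DropletLayout,
    growth: GrowthParams,
    render: RenderParams,
) -> np.ndarray:
    """Colony centers inside the spot, spread so colonies stay distinct.

    Centers are drawn uniformly over a disk of ``placement_radius_fraction``
    of the spot radius, with dart-throwing rejection enforcing a minimum
    pairwise distance of roughly twice the colony radius at half carrying
    capacity (capped at what the disk can pack).  This reproduces the
    observed behaviour that microcolonies do not merge until the droplet is
    nearly saturated; when the requested separation cannot be packed the
    constraint is relaxed geometrically.
    """
    cy, cx = layout.frame_center
    if n == 0:
        return np.zeros((0, 2))
    r_place = render.placement_radius_fraction * layout.spot_radius_px
    r_half = math.sqrt(
        render.colony_area_per_biomass * growth.carrying_capacity / (2.0 * n * math.pi)
    )
    d_target = 2.0 * r_half + 2.0
    d_feasible = 1.9 * r_place / math.sqrt(n)
    d_min = min(d_target, d_feasible)

    pts = np.empty((n, 2))
    k = 0
    fails = 0
    while k < n:
        u = rng.random()
        theta = rng.random() * 2.0 * math.pi
        r = r_place * math.sqrt(u)
        cy_i = cy + r * math.sin(theta)
        cx_i = cx + r * math.cos(theta)
        if k > 0:
            dmin = float(
                np.min(np.hypot(pts[:k, 0] - cy_i, pts[:k, 1] - cx_i))
            )
            if dmin < d_min:
                fails += 1
                if fails >= 200:
                    d_min *= 0.8
                    fails = 0
                continue
        pts[k] = (cy_i, cx_i)
        k += 1
        fails = 0
    return pts


def build_scene(
    layout: DropletLayout,
    counts,
    groups=None,
    *,
    growth: GrowthParams | None = None,
    render: RenderParams | None = None,
    times_h: np.ndarray | None = None,
    seed: int = 0,
    substep_h: float = 0.05,
) -> SyntheticScene:
    """Build a scene from explicit per-droplet cell counts.

    ``counts`` has one entry per droplet (row-major order); ``groups``
    optionally labels each droplet with its nominal cells-per-droplet (for
    grouping in the analysis), defaulting to the actual count.
    """
    growth = growth or GrowthParams()
    render = render or RenderParams()
    times = default_times() if times_h is None else np.asarray(times_h, dtype=float)
    counts = [int(c) for c in counts]
    if len(counts) != layout.n_droplets:
        raise ConfigurationError(
            f"{len(counts)} counts for a layout of {layout.n_droplets} droplets"
        )
    if any(c < 0 for c in counts):
        raise ConfigurationError("cell counts must be >= 0")
    if groups is None:
        groups = [float(c) for c in counts]

    droplets = []
    for did, count in enumerate(counts):
        row, col = layout.position(did)
        rng = np.random.default_rng([int(seed), did, 0])
        illum = rng.uniform(render.illumination_low, render.illumination_high)
        lags = _sample_lags(rng, count, growth)
        centers = _place_colonies(rng, count, layout, growth, render)
        droplets.append(
            DropletTruth(
                droplet_id=did,
                row=row,
                col=col,
                group=float(groups[did]),
                cell_count=count,
                lags_h=lags,
                centers_px=centers,
                illumination=illum,
            )
        )
    return SyntheticScene(
        layout=layout,
        times_h=times,
        growth=growth,
        render=render,
        droplets=droplets,
        seed=int(seed),
        substep_h=substep_h,
    )


def plan_experiment(
    layout: DropletLayout,
    concentrations,
    droplets_per_concentration: int,
    volume_ul: float = 1.0,
    *,
    seed: int = 0,
    growth: GrowthParams | None = None,
    render: RenderParams | None = None,
    times_h: np.ndarray | None = None,
    substep_h: float = 0.05,
) -> SyntheticScene:
    """Plan a multi-concentration experiment on one array.

    Droplets are assigned to concentration groups in row-major blocks (the
    four-concentration reference design puts six droplets of 10³, 10², 10
    and 1 cells/μl on a 4 × 6 array) and each droplet's cell count is a
    Poisson draw with λ = concentration × volume.
    """
    concentrations = list(concentrations)
    if len(concentrations) * droplets_per_concentration != layout.n_droplets:
        raise ConfigurationError(
            f"{len(concentrations)} concentrations x {droplets_per_concentration} "
            f"droplets do not fill a {layout.n_rows}x{layout.n_cols} array"
        )
    counts: list[int] = []
    group_labels: list[float] = []
    for gi, conc in enumerate(concentrations):
        lam = occupancy.lambda_from_loading(conc, volume_ul)
        model = occupancy.OccupancyModel(lam)
        draws = occupancy.sample_counts(model, droplets_per_concentration, [int(seed), 1000 + gi])
        counts.extend(int(c) for c in draws)
        group_labels.extend([lam] * droplets_per_concentration)
    return build_scene(
        layout,
        counts,
        group_labels,
        growth=growth,
        render=render,
        times_h=times_h,
        seed=seed,
        substep_h=substep_h,
    )


# ---------------------------------------------------------------------------
# latent dynamics
# ---------------------------------------------------------------------------


def _refine_times(times: np.ndarray, substep: float):
    """Dense integration grid that contains every frame time exactly."""
    segs = []
    idx = [0]
    pos = 0
    for i in range(len(times) - 1):
        nsub = max(1, int(math.ceil((times[i + 1] - times[i]) / substep - 1e-9)))
        segs.append(np.linspace(times[i], times[i + 1], nsub + 1)[:-1])
        pos += nsub
        idx.append(pos)
    segs.append(np.array([times[-1]]))
    return np.concatenate(segs), np.asarray(idx)


def _integrate(
    cell_count: int,
    lags: np.ndarray,
    growth: GrowthParams,
    dense_times: np.ndarray,
):
    """Integrate the shared-capacity logistic system on the dense grid.

    Uses per-step exponential factors b ← b·exp(μ h (1 − B/K)), which is
    exact in the pure-exponential limit (K → ∞) for any step size and keeps
    the total biomass below K for all steps.  Returns the (cells × times)
    biomass array and the plateau time (first grid time with B ≥ 0.99 K,
    NaN if never reached).  With sporulation, biomass freezes at the plateau.
    """
    m = len(dense_times)
    if cell_count == 0:
        return np.zeros((0, m)), math.nan
    lags = np.asarray(lags, dtype=float)
    b = np.full(cell_count, growth.initial_biomass_per_cell, dtype=float)
    out = np.empty((cell_count, m))
    out[:, 0] = b
    mu = growth.specific_growth_rate
    K = growth.carrying_capacity
    plateau = math.nan
    frozen = False
    for j in range(1, m):
        if not frozen:
            h = dense_times[j] - dense_times[j - 1]
            growing = lags <= dense_times[j - 1] + 1e-12
            if np.any(growing):
                fac = math.exp(mu * h * (1.0 - b.sum() / K))
                b = np.where(growing, b * fac, b)
            if math.isnan(plateau) and b.sum() >= 0.99 * K:
                plateau = float(dense_times[j])
                if growth.sporulation:
                    frozen = True
        out[:, j] = b
    return out, plateau


def simulate_biomass(
    cell_count: int,
    lags,
    params: GrowthParams,
    times,
    substep_h: float = 0.05,
) -> np.ndarray:
    """Per-colony biomass trajectories sampled at ``times`` (hours).

    Each founder cell holds its initial biomass until its lag ends, then
    grows logistically against the droplet's shared carrying capacity.
    Returns an array of shape (cell_count, len(times)).
    """
    lags = np.asarray(lags, dtype=float)
    if len(lags) != cell_count:
        raise ValueError(f"expected {cell_count} lags, got {len(lags)}")
    times = np.asarray(times, dtype=float)
    dense, idx = _refine_times(times, substep_h)
    traj, _ = _integrate(cell_count, lags, params, dense)
    return traj[:, idx]


def _alpha_scale(t, plateau: float, growth: GrowthParams):
    """Sporulation attenuation multiplier: 1 before the plateau, then a
    linear relaxation to (1 − rebound_fraction) over the rebound ramp.

    The multiplier scales the absorbed fraction 1 − e^{−τ} (the darkening
    itself), so a rebound_fraction of 0.3 recovers 30% of the attenuation
    at its peak regardless of the optical depth."""
    t = np.asarray(t, dtype=float)
    if not growth.sporulation or math.isnan(plateau):
        return np.ones_like(t)
    prog = np.clip((t - plateau) / growth.rebound_ramp_h, 0.0, 1.0)
    return 1.0 - growth.rebound_fraction * prog


# ---------------------------------------------------------------------------
# ground truth from the noiseless latent signal
# ---------------------------------------------------------------------------


def _latent_normalized_signal(
    scene: SyntheticScene,
    droplet: DropletTruth,
    traj: np.ndarray,
    dense_times: np.ndarray,
    plateau: float,
) -> np.ndarray:
    """Noiseless normalized mean transmission over the measurement disk.

    Analytic: per-colony disk ∩ measurement-disk overlap areas (colony–colony
    overlaps neglected, a good approximation before colonies merge — the
    regime in which the threshold is crossed) attenuated by the Beer–Lambert
    factor, normalized to the initial value.
    """
    rnd = scene.render
    r_meas = rnd.measurement_shrink * scene.layout.spot_radius_px
    area_meas = math.pi * r_meas**2
    if traj.shape[0] == 0:
        return np.ones_like(dense_times)
    cy, cx = scene.layout.frame_center
    d = np.hypot(droplet.centers_px[:, 0] - cy, droplet.centers_px[:, 1] - cx)
    radii = np.sqrt(rnd.colony_area_per_biomass * traj / math.pi)
    overlap = disk_overlap_area(d[:, None], radii, r_meas)
    absorb = (1.0 - math.exp(-rnd.colony_optical_depth)) * _alpha_scale(
        dense_times, plateau, scene.growth
    )
    signal = 1.0 - overlap.sum(axis=0) * absorb / area_meas
    return signal / signal[0]


def _first_crossing(times: np.ndarray, values: np.ndarray, threshold: float):
    """Linear-interpolated first downward crossing of ``threshold``."""
    below = values < threshold
    if not np.any(below):
        return math.nan
    i = int(np.argmax(below))
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    v0, v1 = values[i - 1], values[i]
    return float(t0 + (v0 - threshold) / (v0 - v1) * (t1 - t0))


def _merge_time(
    scene: SyntheticScene, droplet: DropletTruth, traj_frames: np.ndarray
) -> float:
    """First frame time at which any two colony disks touch (NaN if never,
    or if the droplet holds more than 64 colonies)."""
    n = traj_frames.shape[0]
    if n < 2:
        return math.nan
    if n > 64:
        return math.nan
    c = droplet.centers_px
    dmat = np.hypot(c[:, None, 0] - c[None, :, 0], c[:, None, 1] - c[None, :, 1])
    iu = np.triu_indices(n, k=1)
    radii = np.sqrt(scene.render.colony_area_per_biomass * traj_frames / math.pi)
    rsum = radii[iu[0], :] + radii[iu[1], :]  # (pairs, T)
    touching = (rsum > dmat[iu][:, None]).any(axis=0)
    if not touching.any():
        return math.nan
    return float(scene.times_h[int(np.argmax(touching))])


def _checkpoint_frame(
    scene: SyntheticScene,
    droplet: DropletTruth,
    traj_frames: np.ndarray,
    merge_time: float,
    countable_area_px: float = COUNTABLE_COLONY_AREA_PX,
):
    """First frame at which every colony is countable but none have merged.

    A colony is countable once its area reaches ``countable_area_px``.
    Empty droplets return frame 0; returns None if no such frame exists.
    """
    if traj_frames.shape[0] == 0:
        return 0
    areas = scene.render.colony_area_per_biomass * traj_frames
    big_enough = (areas >= countable_area_px).all(axis=0)
    ok = big_enough
    if not math.isnan(merge_time):
        ok = ok & (scene.times_h < merge_time)
    if not ok.any():
        return None
    return int(np.argmax(ok))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_stack(scene: SyntheticScene, threshold: float = 0.99):
    """Render the scene to a frame stack plus its ground-truth table.

    Returns
    -------
    stack : ndarray, uint8, shape (n_droplets, n_frames, H, W)
        Bright-field frames, one field of view per droplet: the spot disk at
        background × per-droplet illumination, darker oil outside, colonies
        as Beer–Lambert-attenuated disks with area proportional to biomass
        (clipped to the spot), plus additive Gaussian noise.
    truth : pandas.DataFrame
        One row per droplet with the seeded ground truth and the latent
        threshold-crossing / plateau / merge / checkpoint quantities.

    Each colony multiplies the in-spot transmission by 1 − cov·(1 − e^{−τ}),
    where cov is its area-exact per-pixel coverage: linear in covered area
    for isolated (even sub-pixel) colonies, and equivalent to adding optical
    depths where grown colonies fully overlap.
    """
    layout = scene.layout
    rnd = scene.render
    H, W = layout.frame_shape
    cy, cx = layout.frame_center
    spot = disk_mask((H, W), (cy, cx), layout.spot_radius_px)
    n_frames = len(scene.times_h)
    dense, frame_idx = _refine_times(scene.times_h, scene.substep_h)
    tau = rnd.colony_optical_depth
    stamp_max_r = 16.0  # larger colonies are rendered with exact centers

    stack = np.empty((layout.n_droplets, n_frames, H, W), dtype=np.uint8)
    rows = []
    frame_diag = math.hypot(H, W)

    for drop in scene.droplets:
        traj, plateau = _integrate(drop.cell_count, drop.lags_h, scene.growth, dense)
        traj_frames = traj[:, frame_idx]
        alpha = _alpha_scale(scene.times_h, plateau, scene.growth)

        base = np.full((H, W), rnd.oil_intensity, dtype=np.float32)
        base[spot] = rnd.background_intensity * drop.illumination
        noise_rng = np.random.default_rng([scene.seed, drop.droplet_id, 1])
        clipped_warned = False
        centers_int = np.rint(drop.centers_px).astype(int)

        for t in range(n_frames):
            frame = base.copy()
            if drop.cell_count > 0:
                atten = np.ones((H, W), dtype=np.float32)
                absorb = (1.0 - math.exp(-tau)) * alpha[t]
                radii = np.sqrt(
                    rnd.colony_area_per_biomass * traj_frames[:, t] / math.pi
                )
                for i in range(drop.cell_count):
                    r = radii[i]
                    if r <= 0:
                        continue
                    if r >= frame_diag:
                        atten *= 1.0 - absorb
                        continue
                    if r <= stamp_max_r:
                        cov, half = coverage_stamp(r)
                        iy, ix = centers_int[i]
                        y0, y1 = iy - half, iy + half + 1
                        x0, x1 = ix - half, ix + half + 1
                        if y0 < 0 or x0 < 0 or y1 > H or x1 > W:
                            sy0, sx0 = max(-y0, 0), max(-x0, 0)
                            sy1 = cov.shape[0] - max(y1 - H, 0)
                            sx1 = cov.shape[1] - max(x1 - W, 0)
                            cov = cov[sy0:sy1, sx0:sx1]
                            y0, x0 = max(y0, 0), max(x0, 0)
                            y1, x1 = min(y1, H), min(x1, W)
                        atten[y0:y1, x0:x1] *= 1.0 - absorb * cov
                        continue
                    ci = drop.centers_px[i]
                    if not clipped_warned and (
                        ci[0] - r < -0.5
                        or ci[1] - r < -0.5
                        or ci[0] + r > H - 0.5
                        or ci[1] + r > W - 0.5
                    ):
                        warnings.warn(
                            f"droplet {drop.droplet_id}: colony disk exceeds the "
                            f"frame bounds and is clipped",
                            stacklevel=2,
                        )
                        clipped_warned = True
                    cov, sl = disk_coverage_patch((H, W), ci, r)
                    atten[sl] *= 1.0 - absorb * cov
                dark = spot & (atten < 1.0)
                if dark.any():
                    frame[dark] *= atten[dark]
            if rnd.noise_sd > 0:
                frame = frame + rnd.noise_sd * noise_rng.standard_normal(
                    (H, W), dtype=np.float32
                )
            stack[drop.droplet_id, t] = np.clip(np.rint(frame), 0, 255).astype(np.uint8)

        signal = _latent_normalized_signal(scene, drop, traj, dense, plateau)
        t_true = _first_crossing(dense, signal, threshold)
        merge = _merge_time(scene, drop, traj_frames)
        checkpoint = _checkpoint_frame(scene, drop, traj_frames, merge)
        rows.append(
            {
                "droplet_id": drop.droplet_id,
                "row": drop.row,
                "col": drop.col,
                "group": drop.group,
                "cell_count": drop.cell_count,
                "illumination": drop.illumination,
                "lags_h": ";".join(f"{x:.6g}" for x in drop.lags_h),
                "colony_centers_px": ";".join(
                    f"{r:.2f}:{c:.2f}" for r, c in np.asarray(drop.centers_px).reshape(-1, 2)
                ),
                "true_threshold_time_h": t_true,
                "plateau_time_h": plateau,
                "merge_time_h": merge,
                "checkpoint_frame": checkpoint,
            }
        )
    truth = pd.DataFrame(rows)
    return stack, truth


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def write_scene(scene: SyntheticScene, stack: np.ndarray, truth: pd.DataFrame, outdir):
    """Write a rendered scene to ``outdir``.

    Produces ``droplet_NN.tif`` (multi-page grayscale TIFF, one per droplet),
    ``ground_truth.csv`` and ``scene.json`` (full configuration + seed).
    Returns the list of written paths.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = []
    for did in range(stack.shape[0]):
        p = os.path.join(outdir, f"droplet_{did:02d}.tif")
        tifffile.imwrite(p, stack[did], photometric="minisblack")
        paths.append(p)
    gt = os.path.join(outdir, "ground_truth.csv")
    truth.to_csv(gt, index=False)
    paths.append(gt)
    cfg = os.path.join(outdir, "scene.json")
    with open(cfg, "w") as fh:
        json.dump(scene.to_dict(), fh, indent=1, sort_keys=True)
    paths.append(cfg)
    return paths


def load_scene(outdir):
    """Read back a written scene directory → (scene, stack, truth)."""
    with open(os.path.join(outdir, "scene.json")) as fh:
        scene = SyntheticScene.from_dict(json.load(fh))
    frames = []
    for did in range(scene.layout.n_droplets):
        frames.append(tifffile.imread(os.path.join(outdir, f"droplet_{did:02d}.tif")))
    stack = np.stack(frames, axis=0)
    truth = pd.read_csv(os.path.join(outdir, "ground_truth.csv"))
    return scene, stack, truth
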