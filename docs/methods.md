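# Methods

This note documents the models behind `moca`: what the synthetic-data
generator simulates and why, the analysis definitions, the numerical
choices, and what the package's passing tests do and do not establish about
real data.

## Occupancy model

Cell capture during droplet dispensing is modeled as Poisson with mean
occupancy λ = concentration (cells/μl) × volume (μl). The module exposes
the pmf (evaluated in log space via `scipy.stats.poisson`, stable at the
10³ cells/μl loading), the multicell tail P(K ≥ 2) = 1 − e^(−λ)(1 + λ),
and the inverse design problem λe^(−λ) = p, solved with bracketed
root-finding (Brent, xtol 10⁻¹²) on either side of the maximizer λ = 1.
The maximum attainable single-cell fraction is e^(−1) ≈ 0.3679; targets
above it raise `InfeasibleTargetError`. At λ = 0.25 the tail P(K ≥ 2) is
2.65% and P(K = 2) is 2.43%; both are exposed, and neither is forced to
agree with coarser rounded figures ("around 2%") sometimes quoted for this
dilution.

No aggregation/clumping correction and no volume-metering error are
modeled: occupancy is exactly Poisson by construction.

## Synthetic scene

### Geometry

The default layout is a 4 × 6 grid of 3.18-mm hydrophilic spots holding
1-μl droplets, imaged one field of view per droplet at 100 px/mm (spot
radius 159 px). The frame side is odd (383 px) so the spot center falls on
a pixel center, with a 20% margin around the spot. Outside the spot the
frame renders a darker constant (oil, 120 gray); the spot renders at a
background of 200 gray times a per-droplet illumination multiplier drawn
uniformly from [0.9, 1.1] — the droplet-to-droplet light variation that
initial-value normalization is designed to cancel.

### Growth dynamics

Each founder cell starts a colony of biomass b₀ = 1 (nominal cell units)
that stays dormant until a cell-specific lag ends; lags are lognormal with
arithmetic mean 2 h and sd 1 h by default (heterogeneous exit from
dormancy). Growing colonies follow a shared-capacity logistic system

    db_i/dt = μ b_i (1 − Σ_j b_j / K),

with specific rate μ = 0.7 h⁻¹ (doubling time ≈ 1 h) and droplet carrying
capacity K = 1.5·10⁶ — roughly the cell count of a saturated microliter
culture at 1.5·10⁹ cells/ml. Integration uses per-step exponential factors
b ← b·exp(μh(1 − B/K)) on a grid of ≤ 0.05-h substeps refined from the
frame times; this is exact in the pure-exponential limit for any step size
and keeps ΣB ≤ K for all steps. Cells whose lag ends mid-step begin growing
at the next substep (bias ≤ 0.05 h).

With `sporulation=True`, once total biomass first reaches 0.99 K (the
"plateau") counts freeze and the optical attenuation relaxes linearly to
(1 − rebound_fraction) of its peak over `rebound_ramp_h` (default 6 h):
cells shrink without dying, so the droplet brightens after the peak. The
multiplier scales the absorbed fraction 1 − e^(−τ) rather than the optical
depth τ, so `rebound_fraction = 0.3` recovers 30% of the darkening at its
peak regardless of τ; scaling τ instead would make the visible rebound
nearly vanish for strongly absorbing colonies and depend on droplet
geometry in a way the rebound parameter is not meant to encode.

### Optics

Each colony is a disk centered at its seeded position with area
proportional to biomass (0.03 px² per cell unit; a saturated droplet's
colonies total ≈ 45,000 px², ~70% of the measurement disk). A colony
multiplies the in-spot transmission by 1 − cov·(1 − e^(−τ)), where τ = 2.5
is the interior optical depth and cov is an area-exact antialiased
coverage: stamp shapes are cached on a 0.05-px radius grid and rescaled so
per-pixel coverage sums to exactly πr². For isolated colonies — including
sub-pixel ones, which carry the 0.99 crossing at the 10³ loading — the
rendered absorption is therefore *linear* in colony area and agrees with
the analytic ground-truth signal; where colonies overlap the factors
multiply (optical depths add). Colonies are confined to the spot disk.
Gaussian camera noise (sd 2 gray) is added per pixel before quantization to
8 bits; the noise also dithers the quantizer, so frame means are unbiased.

These optical constants are free parameters of the generator chosen to give
realistic-looking records (detection of the 1% transmission drop at a few
×10⁴ cells; plateau transmissions of 0.3–0.65), not claims about any
instrument. Diffraction, meniscus lensing, motility, oxygen gradients and
cross-droplet effects are out of scope.

### Colony placement

Centers are drawn uniformly over a disk of 80% of the spot radius (avoiding
rim artifacts), with a dart-throwing minimum-separation rule: the target
separation is twice the colony radius at half carrying capacity (+2 px),
capped at what the disk can pack (≈1.9·R/√n) and relaxed geometrically if
saturated. This reproduces the observed behaviour that each founder cell
develops its own microcolony and colonies do not merge until the droplet
approaches saturation; independent uniform placement cannot guarantee that
for any pair of colonies. Placement is therefore *not* a homogeneous
spatial Poisson process — a deliberate deviation documented here.

### Ground truth

Per droplet the generator records: cell count, lags, colony centers,
illumination; the **true threshold-crossing time**, computed from the
noiseless latent signal — per-colony disk ∩ measurement-disk overlap areas
(circle–circle intersection) times the absorbed fraction, normalized to its
initial value, interpolated on the 0.05-h grid. Colony–colony overlaps are
neglected in this analytic signal; they are zero before the merge time, and
the 0.99 crossing always happens far earlier. Also recorded: the plateau
time (first grid time with B ≥ 0.99 K), the merge time (first frame where
any two colony disks touch; computed only for ≤ 64 colonies, NaN above),
and a **checkpoint frame** — the first frame at which every colony has
reached 200 px² (10× the counting `min_area`) but none have merged, i.e.
the frame where microcolony counting is meaningful.

## Extraction

One field of view per droplet is the native data model. ROIs come either
from the layout geometry ("grid") or from detection: threshold the first
frame at its 75th intensity percentile, keep the largest 8-connected
component (error if it is the whole frame — no contrast — or covers < 5%
of it), center = centroid, radius = √(area/π). Transmission is the mean
gray level over a measurement disk shrunk to 90% of the ROI radius; the
rim is excluded because the hydrophilic/hydrophobic boundary produces edge
artifacts. Pixels outside the disk never influence the series. The
percentile threshold is appropriate for these bright-spot-on-dark-oil
frames where the spot fills ≳25% of the frame; it is not a general-purpose
detector.

Microcolony counting thresholds at 0.85× the median in-disk intensity
(median-relative, hence insensitive to illumination multipliers), labels
8-connected components and discards those below 20 px². Counts are
meaningful only while the median still reflects background — i.e. before
colony coverage approaches half of the disk — which is exactly the regime
the checkpoint frame identifies.

## Growth analytics

* **Normalization**: divide by the mean of the first `baseline_frames`
  (default 1) values, so every curve starts at exactly 1.
* **Threshold growth time**: first pair of frames straddling 0.99, linearly
  interpolated — sub-frame resolution, deterministic, applied to the *raw*
  normalized curve (no smoothing), since the 0.01-h precision of reported
  threshold times implies interpolation rather than first-frame-below.
* **Growth classification**: grew iff the threshold is crossed *and* the
  final 3-frame-median-smoothed value is ≤ 0.95; the sustained-drop guard
  rejects single-frame noise dips. In assembled results, `grew` ⇔ a
  threshold time is present; absent times are encoded as missing values,
  never sentinels.
* **Rebound detection** (on grown droplets): global minimum of the smoothed
  curve; flagged if the curve later rises ≥ 0.05 and stays above
  (min + 0.025) for ≥ 6 consecutive frames; onset is the time of the
  minimum, which coincides with the population plateau in sporulating
  scenes.
* **Group summaries**: per nominal concentration, counts and Tukey box-plot
  statistics (linear-interpolation quantiles, 1.5×IQR whiskers, outliers
  beyond); a group where nothing grew reports counts with absent statistics.
* **Inoculum fit**: least squares of threshold time against
  log₁₀(nominal cells per droplet) over grown droplets. The log₁₀ axis is a
  modeling choice: exponential growth to a fixed detection biomass predicts
  t = ln(B_th/N₀)/μ, i.e. a slope of −ln(10)/μ hours per decade.

## Pipeline and reproducibility

All randomness flows through numpy's seeded PCG64 generators keyed by
(seed, droplet, stream), so a config plus seed reproduces stacks and tables
bit-identically; the run manifest records the config, seed, generator name
and SHA-256 of every output. Scenes serialize to JSON, stacks to multi-page
grayscale TIFF, tables to CSV, configs to YAML validated by pydantic
models.

## Problem sizes and what the tests show

The test suite and the acceptance script run the reference design (24
droplets × 145 frames, ~0.5 GB of frames) once, a 36-droplet single-cell
scene, and several 1–4-droplet scenes; the full suite completes in a couple
of minutes on one CPU. Passing tests establish that the *pipeline* recovers
the generator's ground truth under the generator's assumptions (Poisson
occupancy, logistic growth with lognormal lags, linear-in-area optics,
Gaussian noise, still droplets). They do not validate those assumptions
against real micrographs: real instruments add focus drift, stage error,
meniscus optics, condensation and debris that this generator deliberately
omits, and threshold times measured on real arrays (e.g. for marine
isolates spanning ~9–31 h) depend on species, medium and temperature that
the defaults do not attempt to match.
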