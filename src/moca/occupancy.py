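"""Poisson statistics of cell loading into droplet arrays.

When a cell suspension of concentration ``c`` (cells/μl) is dispensed into
droplets of volume ``v`` (μl), the number of cells trapped in a droplet is a
Poisson random variable with mean occupancy ``λ = c · v``.  This module holds
the loading model and the handful of derived quantities that drive a dilution
design: the occupancy pmf, the multicell tail P(K ≥ 2), the inverse problem of
choosing λ for a wanted single-cell fraction, and reproducible count sampling
for the synthetic-scene generator.

The single-cell fraction P(K = 1) = λ e^{−λ} peaks at λ = 1 with value
e^{−1} ≈ 0.368; any target below that is reached by two λ values, one on each
side of 1 (the ``branch`` argument of the solver selects which).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "MAX_SINGLE_CELL_FRACTION",
    "OccupancyModel",
    "InfeasibleTargetError",
    "lambda_from_loading",
    "occupancy_pmf",
    "occupancy_table",
    "single_cell_probability",
    "multicell_probability",
    "solve_lambda_for_single_fraction",
    "sample_counts",
]

#: Maximum attainable single-cell fraction, e^{-1}, reached at λ = 1.
MAX_SINGLE_CELL_FRACTION = math.exp(-1.0)


class InfeasibleTargetError(ValueError):
    """A requested single-cell fraction exceeds the Poisson maximum e^{-1}."""


def lambda_from_loading(concentration: float, volume: float) -> float:
    """Mean cells per droplet from loading concentration and droplet volume.

    Parameters
    ----------
    concentration : float
        Cell density of the loaded suspension, cells/μl.  Must be ≥ 0.
    volume : float
        Droplet volume, μl.  Must be > 0.

    Returns
    -------
    float
        Mean occupancy λ = concentration × volume, cells per droplet.
    """
    if not np.isfinite(concentration) or concentration < 0:
        raise ValueError(f"concentration must be finite and >= 0, got {concentration}")
    if not np.isfinite(volume) or volume <= 0:
        raise ValueError(f"volume must be finite and > 0, got {volume}")
    return float(concentration) * float(volume)


@dataclass(frozen=True)
class OccupancyModel:
    """Poisson loading model with mean occupancy ``mean_occupancy`` (λ)."""

    mean_occupancy: float

    def __post_init__(self) -> None:
        lam = self.mean_occupancy
        if not np.isfinite(lam) or lam < 0:
            raise ValueError(f"mean_occupancy must be finite and >= 0, got {lam}")

    @classmethod
    def from_loading(cls, concentration: float, volume: float) -> "OccupancyModel":
        """Build the model from a loading concentration (cells/μl) and volume (μl)."""
        return cls(lambda_from_loading(concentration, volume))

    def pmf(self, k) -> float:
        return occupancy_pmf(k, self)

    def multicell_probability(self) -> float:
        return multicell_probability(self)

    def single_cell_probability(self) -> float:
        return single_cell_probability(self)


def _lam(model) -> float:
    if isinstance(model, OccupancyModel):
        return model.mean_occupancy
    lam = float(model)
    if not np.isfinite(lam) or lam < 0:
        raise ValueError(f"mean occupancy must be finite and >= 0, got {lam}")
    return lam


def _check_k(k):
    arr = np.asarray(k)
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"k must be numeric, got {k!r}")
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise ValueError(f"k must be a non-negative integer, got {k!r}")
    return arr.astype(np.int64)


def occupancy_pmf(k, model) -> float | np.ndarray:
    """P(K = k) under Poisson loading, e^{−λ} λ^k / k!.

    Evaluated in log space (via :func:`scipy.stats.poisson`) so that large λ
    such as the 10³ cells/μl loading do not overflow.  ``k`` may be a scalar
    or an integer array.
    """
    karr = _check_k(k)
    lam = _lam(model)
    p = stats.poisson.pmf(karr, lam)
    return float(p) if np.isscalar(k) or karr.ndim == 0 else p


def occupancy_table(model, max_k: int | None = None, tail_mass: float = 1e-9):
    """Occupancy distribution as arrays ``(k, probability)``.

    If ``max_k`` is None the table is truncated adaptively so that the
    omitted upper tail carries at most ``tail_mass`` probability.
    """
    lam = _lam(model)
    if max_k is None:
        max_k = int(stats.poisson.isf(tail_mass, lam)) + 1 if lam > 0 else 0
    ks = np.arange(max_k + 1)
    return ks, stats.poisson.pmf(ks, lam)


def single_cell_probability(model) -> float:
    """P(K = 1) = λ e^{−λ}, the fraction of droplets founded by one cell."""
    return occupancy_pmf(1, model)


def multicell_probability(model) -> float:
    """P(K ≥ 2) = 1 − e^{−λ}(1 + λ), the fraction of droplets with ≥ 2 cells.

    Computed through the Poisson survival function for numerical stability.
    """
    lam = _lam(model)
    return float(stats.poisson.sf(1, lam))


def solve_lambda_for_single_fraction(target: float, branch: str = "low") -> float:
    """Invert P(K = 1) = λ e^{−λ} for λ (dilution design).

    Parameters
    ----------
    target : float
        Wanted single-cell fraction, 0 < target ≤ e^{−1}.
    branch : {"low", "high"}
        ``"low"`` returns the root in (0, 1] (dilute loading, few multicell
        droplets); ``"high"`` the root in [1, ∞) (dense loading).

    Returns
    -------
    float
        λ with λ e^{−λ} = target, to |Δλ| ≤ 1e−10.
    """
    if not np.isfinite(target) or target <= 0:
        raise ValueError(f"target single-cell fraction must be > 0, got {target}")
    if branch not in ("low", "high"):
        raise ValueError(f"branch must be 'low' or 'high', got {branch!r}")
    if target > MAX_SINGLE_CELL_FRACTION * (1 + 1e-12):
        raise InfeasibleTargetError(
            f"single-cell fraction {target} exceeds the Poisson maximum "
            f"e^-1 = {MAX_SINGLE_CELL_FRACTION:.6f} (attained at lambda = 1)"
        )
    if target >= MAX_SINGLE_CELL_FRACTION:
        return 1.0

    def f(lam: float) -> float:
        return lam * math.exp(-lam) - target

    if branch == "low":
        lo, hi = 1e-300, 1.0
    else:
        lo, hi = 1.0, 2.0
        while f(hi) > 0:
            hi *= 2.0
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16))


def sample_counts(model, n_droplets: int, seed) -> np.ndarray:
    """Draw ``n_droplets`` independent Poisson(λ) cell counts.

    ``seed`` may be an int, a sequence of ints, or a ``numpy.random.Generator``;
    the default generator is numpy's seeded PCG64, so a fixed seed reproduces
    the draws exactly.
    """
    if n_droplets < 1:
        raise ValueError(f"n_droplets must be >= 1, got {n_droplets}")
    lam = _lam(model)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.poisson(lam, size=int(n_droplets))
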