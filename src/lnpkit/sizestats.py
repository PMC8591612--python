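"""Particle-size distribution statistics for diameter samples.

TEM-style particle counts are summarised by a least-squares Gaussian fit
to the diameter histogram (mean, SD) and by the polydispersity index

    PDI = SD / mean

i.e. the coefficient of variation of the diameter distribution -- note
this is *not* the DLS cumulant PDI, which is a different quantity.
Log-normal summaries convert (median, sigma_log) fit parameters into the
same (mean, SD) moments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "DiameterSample",
    "GaussianFit",
    "gaussian_fit_diameters",
    "pdi",
    "lognormal_summary",
    "lognormal_params_from_moments",
]


@dataclass(frozen=True)
class DiameterSample:
    """A set of measured particle diameters, nm."""

    diameters: np.ndarray
    source: str = ""

    def __post_init__(self):
        d = np.asarray(self.diameters, dtype=float)
        object.__setattr__(self, "diameters", d)
        if d.ndim != 1 or d.size < 1:
            raise InvalidInputError("diameters must be a non-empty 1-D array")
        if np.any(d <= 0):
            raise InvalidInputError("all diameters must be positive")


@dataclass(frozen=True)
class GaussianFit:
    """Gaussian histogram fit result; ``from_moments`` marks the fallback path."""

    mean: float  # nm
    sd: float  # nm
    n_bins: int
    from_moments: bool
    residual_rms: float


def _freedman_diaconis_bins(d: np.ndarray) -> int:
    iqr = np.subtract(*np.percentile(d, [75, 25]))
    if iqr <= 0:
        return 10
    width = 2.0 * iqr / d.size ** (1.0 / 3.0)
    return max(int(np.ceil((d.max() - d.min()) / width)), 5)


def gaussian_fit_diameters(sample: DiameterSample, n_bins: int | None = None) -> GaussianFit:
    """Least-squares Gaussian fit to the diameter histogram.

    Bins the sample into ``n_bins`` equal-width bins (Freedman-Diaconis
    rule when omitted) and fits ``A exp(-(d - mu)^2 / (2 s^2))`` to the bin
    counts.  Samples with fewer than 30 diameters, degenerate histograms or
    a failed fit fall back to plain sample moments (``from_moments=True``).
    """
    d = sample.diameters
    mu0, sd0 = float(d.mean()), float(d.std(ddof=1)) if d.size > 1 else 0.0
    if d.size < 30 or sd0 == 0:
        return GaussianFit(mean=mu0, sd=sd0, n_bins=0, from_moments=True, residual_rms=0.0)
    bins = n_bins if n_bins is not None else _freedman_diaconis_bins(d)
    counts, edges = np.histogram(d, bins=bins)
    centres = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, a, mu, s):
        return a * np.exp(-((x - mu) ** 2) / (2.0 * s**2))

    try:
        popt, _ = optimize.curve_fit(
            gauss, centres, counts, p0=[counts.max(), mu0, sd0], maxfev=5000
        )
        a, mu, s = popt
        s = abs(float(s))
        if not np.isfinite(mu) or s <= 0 or not (d.min() - 3 * sd0 < mu < d.max() + 3 * sd0):
            raise RuntimeError("implausible Gaussian parameters")
        rms = float(np.sqrt(np.mean((gauss(centres, *popt) - counts) ** 2)))
        return GaussianFit(mean=float(mu), sd=s, n_bins=bins, from_moments=False,
                           residual_rms=rms)
    except RuntimeError:
        return GaussianFit(mean=mu0, sd=sd0, n_bins=bins, from_moments=True, residual_rms=0.0)


def pdi(mean: float, sd: float) -> float:
    """Polydispersity index SD/mean (dimensionless, scale-invariant)."""
    if mean <= 0:
        raise InvalidInputError("mean must be positive")
    if sd < 0:
        raise InvalidInputError("sd must be >= 0")
    return sd / mean


def lognormal_summary(median: float, sigma_log: float) -> tuple[float, float]:
    """(mean, SD) of a log-normal diameter distribution from (median, sigma_log).

    mean = median exp(sigma^2/2);  SD = mean sqrt(exp(sigma^2) - 1).
    """
    if median <= 0:
        raise InvalidInputError("median must be positive")
    if sigma_log < 0:
        raise InvalidInputError("sigma_log must be >= 0")
    mean = median * np.exp(sigma_log**2 / 2.0)
    sd = mean * np.sqrt(np.expm1(sigma_log**2))
    return float(mean), float(sd)


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Invert lognormal_summary: (median, sigma_log) giving the stated moments."""
    if mean <= 0 or sd < 0:
        raise InvalidInputError("mean must be positive and sd >= 0")
    if sd == 0:
        return mean, 0.0
    sigma2 = np.log1p((sd / mean) ** 2)
    median = mean * np.exp(-sigma2 / 2.0)
    return float(median), float(np.sqrt(sigma2))
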