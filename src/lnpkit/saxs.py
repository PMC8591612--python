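"""Small-angle X-ray scattering analysis for dilute nanoparticle dispersions.

Implements the two analysis chains applied to absolute-scale 1-D SAXS
curves from lignin nanoparticle (LNP) dispersions:

1. **Form-factor fitting** -- an analytical model of homogeneous spheres
   with a number-weighted log-normal diameter distribution is fitted to
   I(q) by weighted least squares, yielding the mean diameter and SD of
   the particle size distribution.

2. **Invariant / Porod surface-area chain** -- the scattering invariant

       Q = integral_0^inf I(q) q^2 dq

   of a two-phase system equals ``2 pi^2 phi (1-phi) drho^2``, so with a
   known volume fraction phi it fixes the particle/solvent scattering
   contrast drho.  The Porod limit ``K_P = lim I q^4 = 2 pi drho^2 (S/V)``
   then gives the surface-to-volume ratio, and the specific surface area
   follows as ``SSA = (S/V) / (phi rho)``.  The integral requires
   extrapolating the measured curve with the Guinier law at low q and the
   Porod law at high q.

Unit conventions: q in 1/Angstrom; intensities in absolute 1/Angstrom
internally (reduced-data files in 1/mm are converted at ingest,
1 mm^-1 = 1e-7 A^-1); diameters at public interfaces in nm; SLDs quoted
in 1e-6 A^-2; specific surface areas in m^2/g.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import stats

from .constants import ELEMENTS, MM_INV_TO_A_INV, N_AVOGADRO, R_ELECTRON_CM
from .errors import (
    DataQualityError,
    ExtrapolationError,
    FitFailureError,
    InsufficientDataError,
    InvalidInputError,
    PorodInvalidError,
)

__all__ = [
    "ScatteringCurve",
    "SphereLogNormalModel",
    "SphereFitResult",
    "GuinierFit",
    "PorodFit",
    "ExtendedCurve",
    "InvariantChain",
    "Composition",
    "sphere_form_factor",
    "model_intensity",
    "fit_sphere_lognormal",
    "guinier_fit",
    "porod_fit",
    "extrapolate_curve",
    "invariant",
    "contrast_from_invariant",
    "surface_to_volume",
    "specific_surface_area",
    "sphere_ssa",
    "invariant_chain",
    "xray_sld",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ScatteringCurve:
    """Absolute-intensity 1-D SAXS curve.

    q in 1/Angstrom (strictly increasing, positive); intensity in absolute
    1/Angstrom; optional 1-sigma uncertainties in the same unit.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", i)
        if q.ndim != 1 or i.shape != q.shape:
            raise InvalidInputError("q and intensity must be 1-D arrays of equal length")
        if q.size and (np.any(q <= 0) or np.any(np.diff(q) <= 0)):
            raise InvalidInputError("q must be positive and strictly increasing")
        if not np.all(np.isfinite(i)):
            raise InvalidInputError("intensity must be finite")
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            object.__setattr__(self, "sigma", s)
            if s.shape != q.shape or np.any(s <= 0):
                raise InvalidInputError("sigma must match q and be strictly positive")

    def __len__(self):
        return self.q.size

    @classmethod
    def from_mm_inv(cls, q, intensity_mm, sigma_mm=None) -> "ScatteringCurve":
        """Build from intensities in the reduced-data unit 1/mm."""
        sig = None if sigma_mm is None else np.asarray(sigma_mm) * MM_INV_TO_A_INV
        return cls(q, np.asarray(intensity_mm) * MM_INV_TO_A_INV, sig)


@dataclass(frozen=True)
class SphereLogNormalModel:
    """Homogeneous-sphere model with number-weighted log-normal diameters.

    Attributes
    ----------
    median_diameter : median of the diameter distribution, nm
    sigma_log : SD of ln(diameter) (0 = monodisperse)
    volume_fraction : particle volume fraction phi
    contrast : particle/solvent SLD difference drho, 1/Angstrom^2
    background : flat background, absolute 1/Angstrom
    """

    median_diameter: float
    sigma_log: float = 0.0
    volume_fraction: float = 1e-3
    contrast: float = 3.0e-6
    background: float = 0.0

    def __post_init__(self):
        if self.median_diameter <= 0:
            raise InvalidInputError("median_diameter must be positive")
        if self.sigma_log < 0:
            raise InvalidInputError("sigma_log must be >= 0")
        if not 0 < self.volume_fraction < 1:
            raise InvalidInputError("volume_fraction must lie in (0, 1)")

    @property
    def mean_diameter(self) -> float:
        """Number-weighted mean diameter exp(mu + sigma^2/2), nm."""
        return self.median_diameter * np.exp(self.sigma_log**2 / 2.0)

    @property
    def sd_diameter(self) -> float:
        """SD of the number-weighted diameter distribution, nm."""
        return self.mean_diameter * np.sqrt(np.expm1(self.sigma_log**2))


@dataclass(frozen=True)
class GuinierFit:
    """Low-q Guinier description I(q) = I0 exp(-Rg^2 q^2 / 3)."""

    rg: float  # Angstrom
    i0: float  # absolute 1/Angstrom
    q_range: tuple[float, float]

    @property
    def rg_nm(self) -> float:
        return self.rg / 10.0

    def intensity(self, q):
        return self.i0 * np.exp(-(self.rg**2) * np.asarray(q) ** 2 / 3.0)


@dataclass(frozen=True)
class PorodFit:
    """High-q Porod description I(q) = K_P q^-4 + b."""

    porod_constant: float  # 1/Angstrom * (1/Angstrom)^4 = A^-5
    flat_background: float  # absolute 1/Angstrom
    q_range: tuple[float, float]

    def intensity(self, q, include_background: bool = True):
        q = np.asarray(q)
        tail = self.porod_constant / q**4
        return tail + self.flat_background if include_background else tail


@dataclass(frozen=True)
class ExtendedCurve:
    """Measured curve spliced with analytic Guinier head and Porod tail.

    The body carries background-subtracted intensities; the high-q tail is
    kept analytic (K_P q^-4), never gridded.
    """

    q_body: np.ndarray
    intensity_body: np.ndarray  # background-subtracted
    guinier: GuinierFit
    porod: PorodFit
    splice_mismatch_low: float
    splice_mismatch_high: float


@dataclass(frozen=True)
class InvariantChain:
    """Results of the invariant -> contrast -> S/V -> SSA chain."""

    invariant_q: float  # A^-4
    contrast: float  # A^-2
    s_over_v: float  # A^-1
    specific_surface_area: float  # m^2/g
    volume_fraction: float
    mass_density: float  # g/cm^3


@dataclass(frozen=True)
class Composition:
    """Elemental mass fractions plus mass density, for SLD calculations."""

    mass_fractions: dict[str, float]
    mass_density: float  # g/cm^3

    def __post_init__(self):
        if self.mass_density <= 0:
            raise InvalidInputError("mass_density must be positive")
        total = sum(self.mass_fractions.values())
        if not 0.95 <= total <= 1.05:
            raise InvalidInputError(
                f"mass fractions sum to {total:.3f}; expected within [0.95, 1.05]"
            )
        if any(w <= 0 for w in self.mass_fractions.values()):
            raise InvalidInputError("mass fractions must be positive")

    def normalized(self) -> dict[str, float]:
        total = sum(self.mass_fractions.values())
        return {el: w / total for el, w in self.mass_fractions.items()}


# --------------------------------------------------------------------------
# form factor and model intensity
# --------------------------------------------------------------------------


def sphere_form_factor(q, radius: float):
    """Normalised sphere form factor P(q) = [3 (sin x - x cos x)/x^3]^2, x = qR.

    q in 1/Angstrom (scalar or array, >= 0), radius in Angstrom.  P(0) = 1.
    """
    if radius <= 0:
        raise InvalidInputError("radius must be positive")
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise InvalidInputError("q must be non-negative")
    x = q * radius
    # series-safe evaluation: amplitude -> 1 - x^2/10 for x -> 0
    amp = np.ones_like(x)
    small = x < 1e-4
    xs = x[~small]
    amp[~small] = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3
    amp[small] = 1.0 - x[small] ** 2 / 10.0
    return amp**2


_QUAD_ORDER = 151
_QUAD_HALFWIDTH = 5.0  # sigma, below/above the log-space mean
_QUAD_SIGMA_MAX = 1.2  # width beyond which 151 points cannot resolve the integrand
_nodes, _weights = leggauss(_QUAD_ORDER)


def _lognormal_quadrature(median_a: float, sigma_log: float):
    """Gauss-Legendre nodes (diameters, Angstrom) and normalised weights of the
    number-weighted log-normal diameter distribution.

    The log-space interval runs from mu - 5 sigma to mu + 5 sigma + 6 sigma^2:
    the upper extension covers the V^2-weighted mass (the integrand carries
    V(R)^2 ~ e^{6u}, whose effective distribution is shifted by 6 sigma^2),
    which a symmetric +-5 sigma window truncates at the 0.1% level already
    for moderate widths.
    """
    if sigma_log > _QUAD_SIGMA_MAX:
        raise InvalidInputError(
            f"sigma_log = {sigma_log} exceeds {_QUAD_SIGMA_MAX}: fixed-order "
            "quadrature cannot resolve so wide a size distribution"
        )
    mu = np.log(median_a)
    lo = mu - _QUAD_HALFWIDTH * sigma_log
    hi = mu + _QUAD_HALFWIDTH * sigma_log + 6.0 * sigma_log**2
    u = 0.5 * (hi + lo) + 0.5 * (hi - lo) * _nodes
    pdf = np.exp(-((u - mu) ** 2) / (2.0 * sigma_log**2)) / (sigma_log * np.sqrt(2 * np.pi))
    w = _weights * 0.5 * (hi - lo) * pdf
    cover = w.sum()
    if abs(cover - 1.0) > 1e-3:
        raise InvalidInputError(
            f"log-normal quadrature covers only {cover:.5f} of the distribution "
            f"(sigma_log={sigma_log}); distribution too wide for fixed-order quadrature"
        )
    return np.exp(u), w / cover


def model_intensity(q, model: SphereLogNormalModel):
    """Absolute intensity (1/Angstrom) of the sphere/log-normal model.

    I(q) = drho^2 * (phi / <V>) * <V^2 P(q, R)> + background,

    where <.> is the number-weighted average over the log-normal diameter
    distribution (151-point Gauss-Legendre in log space) and the number
    density phi/<V> ties the distribution's total volume to the volume
    fraction.  For sigma_log = 0 this reduces to the monodisperse closed
    form drho^2 phi V P(q, R) + background.
    """
    q = np.asarray(q, dtype=float)
    median_a = model.median_diameter * 10.0  # nm -> Angstrom
    if model.sigma_log == 0.0:
        r = median_a / 2.0
        v = 4.0 / 3.0 * np.pi * r**3
        return (
            model.contrast**2 * model.volume_fraction * v * sphere_form_factor(q, r)
            + model.background
        )
    diam, w = _lognormal_quadrature(median_a, model.sigma_log)
    radii = diam / 2.0
    vols = 4.0 / 3.0 * np.pi * radii**3
    p = np.empty((radii.size, q.size))
    for k, r in enumerate(radii):
        p[k] = sphere_form_factor(q, r)
    mean_v = np.dot(w, vols)
    mean_v2p = (w * vols**2) @ p
    return model.contrast**2 * model.volume_fraction / mean_v * mean_v2p + model.background


# --------------------------------------------------------------------------
# model fitting
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SphereFitResult:
    """Fitted sphere/log-normal model with derived size moments."""

    model: SphereLogNormalModel
    mean_diameter: float  # nm
    sd_diameter: float  # nm
    chi2_reduced: float
    success: bool
    message: str
    covariance: np.ndarray | None = None
    param_names: tuple[str, ...] = field(default=())


_FIT_FIELDS = ("median_diameter", "sigma_log", "volume_fraction", "contrast", "background")


def _guess_median(curve: ScatteringCurve) -> float:
    """Coarse size guess from a Guinier regression on the lowest-q fifth."""
    n = max(6, len(curve) // 5)
    q, i = curve.q[:n], curve.intensity[:n]
    good = i > 0
    if good.sum() < 5:
        return 50.0  # nm, generic fallback
    slope, intercept, *_ = stats.linregress(q[good] ** 2, np.log(i[good]))
    if slope >= 0:
        return 50.0
    rg = np.sqrt(-3.0 * slope)  # Angstrom
    return float(np.sqrt(5.0 / 3.0) * rg * 2.0 / 10.0)  # diameter, nm


def fit_sphere_lognormal(
    curve: ScatteringCurve,
    init: SphereLogNormalModel | None = None,
    fixed: frozenset[str] | set[str] = frozenset({"contrast"}),
    max_restarts: int = 4,
) -> SphereFitResult:
    """Weighted least-squares fit of the sphere/log-normal model to a curve.

    Weights are 1/sigma^2 when the curve carries uncertainties, else 1/I^2.
    ``fixed`` names model fields held at their ``init`` values; by default
    the contrast is fixed (in the dilute limit contrast^2 * phi is a single
    degree of freedom, so the pair cannot be fitted jointly).  Restarts scan
    a coarse grid of median diameters around a Guinier-based guess; the
    lowest reduced chi^2 wins, ties broken by smallest sigma_log.
    """
    if len(curve) < 20 or curve.q[-1] / curve.q[0] < 10.0:
        raise InsufficientDataError(
            "fit requires >= 20 points spanning at least a decade in q"
        )
    unknown = set(fixed) - set(_FIT_FIELDS)
    if unknown:
        raise InvalidInputError(f"unknown fixed fields: {sorted(unknown)}")

    if init is None:
        init = SphereLogNormalModel(
            median_diameter=max(_guess_median(curve), 2.0),
            sigma_log=0.2,
            volume_fraction=1e-3,
        )

    sigma_eff = curve.sigma if curve.sigma is not None else np.maximum(
        np.abs(curve.intensity), 1e-30
    )

    def residual(params):
        m = SphereLogNormalModel(
            median_diameter=params["median_diameter"].value,
            sigma_log=params["sigma_log"].value,
            volume_fraction=params["volume_fraction"].value,
            contrast=params["contrast"].value,
            background=params["background"].value,
        )
        return (model_intensity(curve.q, m) - curve.intensity) / sigma_eff

    # seed phi so that the model matches the lowest-q intensity
    def scaled_phi(median_nm: float) -> float:
        probe = replace(init, median_diameter=median_nm, volume_fraction=1e-3, background=0.0)
        i_model = model_intensity(curve.q[:3], probe).mean()
        i_data = max(curve.intensity[:3].mean(), 1e-30)
        phi = 1e-3 * i_data / max(i_model, 1e-300)
        return float(np.clip(phi, 1e-9, 0.4))

    candidates = [init.median_diameter * f for f in (1.0, 0.5, 0.75, 1.5, 2.0)][
        : max_restarts + 1
    ]
    best = None
    last_exc = None
    for med0 in candidates:
        params = lmfit.Parameters()
        params.add("median_diameter", value=med0, min=0.5, max=1e4)
        params.add("sigma_log", value=max(init.sigma_log, 1e-3), min=0.0, max=1.2)
        params.add("volume_fraction", value=scaled_phi(med0), min=1e-10, max=0.5)
        params.add("contrast", value=init.contrast, min=1e-9)
        params.add("background", value=max(init.background, 0.0), min=0.0)
        for name in fixed:
            params[name].set(value=getattr(init, name), vary=False)
        try:
            out = lmfit.minimize(residual, params, method="leastsq")
        except Exception as exc:  # keep scanning other starts
            last_exc = exc
            continue
        if best is None or out.redchi < best.redchi - 1e-12 or (
            abs(out.redchi - best.redchi) <= 1e-12
            and out.params["sigma_log"].value < best.params["sigma_log"].value
        ):
            best = out
    if best is None:
        raise FitFailureError(f"all fit restarts failed: {last_exc}", last_result=None)

    p = best.params
    fitted = SphereLogNormalModel(
        median_diameter=p["median_diameter"].value,
        sigma_log=p["sigma_log"].value,
        volume_fraction=p["volume_fraction"].value,
        contrast=p["contrast"].value,
        background=p["background"].value,
    )
    varied = tuple(best.var_names)
    result = SphereFitResult(
        model=fitted,
        mean_diameter=fitted.mean_diameter,
        sd_diameter=fitted.sd_diameter,
        chi2_reduced=float(best.redchi),
        success=bool(best.success),
        message=str(best.message),
        covariance=None if best.covar is None else np.asarray(best.covar),
        param_names=varied,
    )
    if not best.success:
        raise FitFailureError(f"fit did not converge: {best.message}", last_result=result)
    return result


# --------------------------------------------------------------------------
# Guinier / Porod / extrapolation / invariant chain
# --------------------------------------------------------------------------

GUINIER_QRG_MAX = 1.3  # community validity convention, emitted as a warning
POROD_WINDOW_DEFAULT = (0.02, 0.1)  # 1/Angstrom


def guinier_fit(curve: ScatteringCurve, q_window: tuple[float, float]) -> GuinierFit:
    """Linear Guinier regression ln I = ln I0 - Rg^2 q^2 / 3 on a q window.

    Warns (does not fail) when q_max * Rg exceeds 1.3 post hoc.
    """
    lo, hi = q_window
    mask = (curve.q >= lo) & (curve.q <= hi) & (curve.intensity > 0)
    if mask.sum() < 5:
        raise InsufficientDataError("Guinier window must contain >= 5 positive points")
    q, i = curve.q[mask], curve.intensity[mask]
    slope, intercept, *_ = stats.linregress(q**2, np.log(i))
    if slope >= 0:
        raise InvalidInputError("Guinier regression has non-negative slope; bad window")
    rg = float(np.sqrt(-3.0 * slope))
    if q.max() * rg > GUINIER_QRG_MAX:
        warnings.warn(
            f"Guinier window extends to q*Rg = {q.max() * rg:.2f} > {GUINIER_QRG_MAX}",
            stacklevel=2,
        )
    return GuinierFit(rg=rg, i0=float(np.exp(intercept)), q_range=(float(q[0]), float(q[-1])))


def porod_fit(
    curve: ScatteringCurve, q_window: tuple[float, float] = POROD_WINDOW_DEFAULT
) -> PorodFit:
    """Fit the Porod plateau I q^4 = K_P + b q^4 on a high-q window.

    The regression is linear in Porod space (uniform weight on I q^4), the
    standard plateau estimator: an unweighted fit of I against q^-4 would be
    dominated by the low-q edge of the window where form-factor fringes are
    largest.  When the curve extends beyond the window, the flat background
    is re-estimated from the top 15% of the measured q range -- where a
    flat background dominates a q^-4 signal -- and K_P refitted with it
    held fixed; the in-window joint estimate of b is poorly conditioned and
    unsafe to extrapolate.
    """
    lo, hi = q_window
    mask = (curve.q >= lo) & (curve.q <= hi)
    if mask.sum() < 5:
        raise InsufficientDataError("Porod window must contain >= 5 points")
    q, i = curve.q[mask], curve.intensity[mask]
    design = np.column_stack([np.ones_like(q), q**4])
    coef, *_ = np.linalg.lstsq(design, i * q**4, rcond=None)
    kp, b = float(coef[0]), float(coef[1])
    tail = curve.q >= max(0.85 * curve.q[-1], hi)
    if tail.sum() >= 5 and kp > 0:
        b = float(np.mean(curve.intensity[tail] - kp / curve.q[tail] ** 4))
        kp = float(np.mean(i * q**4 - b * q**4))
    if kp <= 0:
        raise PorodInvalidError(
            f"fitted Porod constant {kp:.3e} <= 0: wrong window or no sharp interface"
        )
    return PorodFit(porod_constant=kp, flat_background=b, q_range=(float(q[0]), float(q[-1])))


def extrapolate_curve(
    curve: ScatteringCurve,
    guinier: GuinierFit,
    porod: PorodFit,
    splice_tolerance: float = 0.20,
) -> ExtendedCurve:
    """Splice the measured curve with its Guinier head and Porod tail.

    The Porod flat background is subtracted from the body; the tail is kept
    analytic as K_P q^-4.  Relative continuity mismatches at both splice
    points are reported, and a mismatch above ``splice_tolerance`` raises
    ``ExtrapolationError``.  The low-q mismatch compares the Guinier form
    with the first body points; the high-q mismatch compares invariant-
    weighted integrals (body vs K_P q^-2) over the top 15% of the measured
    q range, which averages over form-factor fringes instead of comparing
    at a single point that may sit in a fringe minimum.
    """
    i_sub = curve.intensity - porod.flat_background
    head = slice(0, max(3, min(5, len(curve))))
    m_low = abs(
        np.mean(guinier.intensity(curve.q[head])) - np.mean(i_sub[head])
    ) / max(abs(np.mean(i_sub[head])), 1e-300)
    tail_mask = curve.q >= 0.85 * curve.q[-1]
    qt = curve.q[tail_mask]
    body_int = np.trapezoid(i_sub[tail_mask] * qt**2, qt)
    porod_int = porod.porod_constant * (1.0 / qt[0] - 1.0 / qt[-1])
    m_high = abs(porod_int - body_int) / max(abs(body_int), 1e-300)
    if m_low > splice_tolerance or m_high > splice_tolerance:
        raise ExtrapolationError(
            f"splice mismatch low={m_low:.1%}, high={m_high:.1%} exceeds "
            f"{splice_tolerance:.0%}: Guinier/Porod fits inconsistent with the curve"
        )
    return ExtendedCurve(
        q_body=curve.q,
        intensity_body=i_sub,
        guinier=guinier,
        porod=porod,
        splice_mismatch_low=float(m_low),
        splice_mismatch_high=float(m_high),
    )


def _guinier_head_integral(g: GuinierFit, q1: float) -> float:
    """Closed form of integral_0^q1 I0 exp(-a q^2) q^2 dq with a = Rg^2/3."""
    a = g.rg**2 / 3.0
    if a == 0:
        return g.i0 * q1**3 / 3.0
    from math import erf, exp, pi, sqrt

    return g.i0 * (
        sqrt(pi) * erf(sqrt(a) * q1) / (4.0 * a**1.5) - q1 * exp(-a * q1**2) / (2.0 * a)
    )


def invariant(extended: ExtendedCurve, max_negative_fraction: float = 0.05) -> float:
    """Scattering invariant Q = integral_0^inf I(q) q^2 dq, in A^-4.

    Composite integration: analytic Guinier head on [0, q_min], trapezoidal
    body on the measured grid (background-subtracted), analytic Porod tail
    K_P/q_max beyond the measured range.
    """
    i = extended.intensity_body
    if i.size == 0:
        return 0.0
    neg = np.mean(i < 0)
    if neg > max_negative_fraction:
        raise DataQualityError(
            f"{neg:.0%} of background-subtracted intensities are negative "
            f"(> {max_negative_fraction:.0%}); check background/absolute scaling"
        )
    head = _guinier_head_integral(extended.guinier, float(extended.q_body[0]))
    body = float(np.trapezoid(i * extended.q_body**2, extended.q_body))
    tail = extended.porod.porod_constant / float(extended.q_body[-1])
    return head + body + tail


def contrast_from_invariant(invariant_q: float, volume_fraction: float) -> float:
    """Contrast drho = sqrt(Q / (2 pi^2 phi (1 - phi))), in A^-2."""
    if not 0 < volume_fraction < 1:
        raise InvalidInputError("volume_fraction must lie in (0, 1)")
    if invariant_q < 0:
        raise InvalidInputError("invariant must be >= 0")
    return float(
        np.sqrt(invariant_q / (2.0 * np.pi**2 * volume_fraction * (1.0 - volume_fraction)))
    )


def surface_to_volume(porod_constant: float, contrast: float) -> float:
    """S/V = K_P / (2 pi drho^2), in 1/Angstrom."""
    if contrast <= 0:
        raise InvalidInputError("contrast must be positive")
    return porod_constant / (2.0 * np.pi * contrast**2)


def specific_surface_area(
    s_over_v: float, volume_fraction: float, mass_density: float
) -> float:
    """SSA = (S/V) / (phi rho) converted from A^-1 and g/cm^3 to m^2/g."""
    if s_over_v < 0 or volume_fraction <= 0 or mass_density <= 0:
        raise InvalidInputError("s_over_v >= 0 and positive phi, rho required")
    # A^-1 = 1e10 m^-1; g/cm^3 = 1e6 g/m^3  ->  factor 1e4
    return s_over_v * 1.0e4 / (volume_fraction * mass_density)


def sphere_ssa(diameter_nm: float, mass_density: float) -> float:
    """Specific surface area 6/(d rho) of smooth solid spheres, m^2/g."""
    if diameter_nm <= 0 or mass_density <= 0:
        raise InvalidInputError("diameter and density must be positive")
    return 6.0e3 / (diameter_nm * mass_density)


def invariant_chain(
    curve: ScatteringCurve,
    volume_fraction: float,
    mass_density: float,
    guinier_window: tuple[float, float] | None = None,
    porod_window: tuple[float, float] = POROD_WINDOW_DEFAULT,
) -> InvariantChain:
    """Run the full invariant -> contrast -> S/V -> SSA chain on one curve."""
    if guinier_window is None:
        guinier_window = (float(curve.q[0]), float(curve.q[max(5, len(curve) // 10)]))
    g = guinier_fit(curve, guinier_window)
    p = porod_fit(curve, porod_window)
    ext = extrapolate_curve(curve, g, p)
    q_inv = invariant(ext)
    drho = contrast_from_invariant(q_inv, volume_fraction)
    sv = surface_to_volume(p.porod_constant, drho)
    ssa = specific_surface_area(sv, volume_fraction, mass_density)
    return InvariantChain(
        invariant_q=q_inv,
        contrast=drho,
        s_over_v=sv,
        specific_surface_area=ssa,
        volume_fraction=volume_fraction,
        mass_density=mass_density,
    )


# --------------------------------------------------------------------------
# scattering length density from composition
# --------------------------------------------------------------------------


def xray_sld(composition: Composition, anomalous: bool = True) -> float:
    """X-ray scattering length density of a material, in 1e-6 A^-2.

    SLD = r_e N_A rho sum_i w_i (Z_i + f'_i) / A_i with mass fractions w_i
    normalised to 1.  Real anomalous corrections f' at Cu K-alpha are
    applied by default (they matter at the 0.5% level for O and S).
    """
    total = 0.0
    for el, w in composition.normalized().items():
        if el not in ELEMENTS:
            raise InvalidInputError(f"unknown element {el!r} in composition")
        z, a, fp = ELEMENTS[el]
        total += w * (z + (fp if anomalous else 0.0)) / a
    sld_cm2 = R_ELECTRON_CM * N_AVOGADRO * composition.mass_density * total  # cm^-2
    return sld_cm2 * 1.0e-16 * 1.0e6  # -> A^-2, quoted in 1e-6 A^-2
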