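"""Correlation-diffusion forward model for diffuse speckle contrast.

Photons multiply scattered by a homogeneous semi-infinite turbid medium carry
an electric-field autocorrelation ``g1(rho, tau)`` whose decay rate is set by
the motion of scatterers (red blood cells, modelled as Brownian with effective
diffusion coefficient ``alpha_db``).  A camera integrating the speckle pattern
over an exposure ``T`` sees a squared spatial speckle contrast

    kappa^2(rho, T) = (2 beta / T) * int_0^T (1 - tau/T) g1(rho, tau)^2 dtau

so faster scatterer motion (higher flow) washes out contrast.  This module
evaluates ``g1`` in the extrapolated-boundary image-source geometry and the
exposure integral above by adaptive quadrature.

Units: all lengths in mm, times in s, ``alpha_db`` in mm^2/s, ``k0`` in 1/mm.
Constructors accept the field-customary nm/ms units and convert.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate

__all__ = [
    "OpticalProperties",
    "FlowParams",
    "SemiInfiniteGeometry",
    "wavenumber",
    "effective_reflection",
    "fresnel_reflection_integral",
    "g1_semi_infinite",
    "speckle_contrast_sq",
    "exposure_integrated_contrast",
    "contrast_vs_flow_curve",
]

NM_PER_MM = 1e6

# Degree-8 Chebyshev fit (domain n in [1, 1.6]) of the unpolarized
# Fresnel-integral effective reflection coefficient; max abs error 4.1e-4
# against the numerical integral over the fit domain.
_REFF_CHEB = np.polynomial.Chebyshev(
    [
        0.3553948717391,
        0.3146932322476,
        -0.04416482771636,
        0.0009262441985164,
        0.002127580742279,
        -0.00109909441936,
        0.0004718902724162,
        -0.0001895370076529,
        9.42480241104e-05,
    ],
    domain=[1.0, 1.6],
)


@dataclass(frozen=True)
class OpticalProperties:
    """Static tissue optics.

    Parameters
    ----------
    mua : float
        Absorption coefficient, 1/mm.
    musp : float
        Reduced scattering coefficient, 1/mm.
    n : float
        Refractive index of the medium (>= 1).
    wavelength : float
        Vacuum wavelength in mm.  Use :meth:`with_wavelength_nm` or the
        ``wavelength_nm`` keyword of :func:`optical_properties` helpers when
        thinking in nm; 785 nm == 7.85e-4 mm.
    """

    mua: float
    musp: float
    n: float = 1.33
    wavelength: float = 785.0 / NM_PER_MM

    def __post_init__(self) -> None:
        if not self.mua > 0:
            raise ValueError(f"mua must be > 0, got {self.mua}")
        if not self.musp > 0:
            raise ValueError(f"musp must be > 0, got {self.musp}")
        if not self.n >= 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not self.wavelength > 0:
            raise ValueError(f"wavelength must be > 0, got {self.wavelength}")

    @classmethod
    def typical_tissue(cls, wavelength_nm: float = 785.0) -> "OpticalProperties":
        """Tissue-mimicking defaults: mua=0.01/mm, musp=1/mm, n=1.33."""
        return cls(mua=0.01, musp=1.0, n=1.33, wavelength=wavelength_nm / NM_PER_MM)

    @property
    def wavelength_nm(self) -> float:
        return self.wavelength * NM_PER_MM


@dataclass(frozen=True)
class FlowParams:
    """Dynamic scatterer parameters.

    ``alpha_db`` is the effective Brownian diffusion coefficient of the moving
    scatterers in mm^2/s (the blood-flow index of the correlation-diffusion
    model); ``beta`` is the coherence factor of the collection optics, which
    bounds kappa^2 from above.
    """

    alpha_db: float
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha_db < 0:
            raise ValueError(f"alpha_db must be >= 0, got {self.alpha_db}")
        if not 0 < self.beta <= 1:
            raise ValueError(f"beta must be in (0, 1], got {self.beta}")


def wavenumber(optics: OpticalProperties) -> float:
    """Optical wavenumber in the medium, k0 = 2 pi n / lambda, 1/mm."""
    return 2.0 * math.pi * optics.n / optics.wavelength


def _unpolarized_fresnel(theta: float, n: float) -> float:
    # internal incidence (medium n -> air); total internal reflection past
    # the critical angle
    sin_t = math.sin(theta)
    if n * sin_t >= 1.0:
        return 1.0
    cos_i = math.cos(theta)
    cos_t = math.sqrt(1.0 - (n * sin_t) ** 2)
    r_s = ((n * cos_i - cos_t) / (n * cos_i + cos_t)) ** 2
    r_p = ((n * cos_t - cos_i) / (n * cos_t + cos_i)) ** 2
    return 0.5 * (r_s + r_p)


def fresnel_reflection_integral(n: float) -> float:
    """Effective reflection coefficient by direct angular integration.

    R_eff = (R_phi + R_j) / (2 - R_phi + R_j) with the fluence and flux
    moments of the unpolarized Fresnel reflectance over the internal
    hemisphere.  Exact up to quadrature error; slower than the fitted
    polynomial used by default.
    """
    if n < 1:
        raise ValueError(f"refractive index ratio must be >= 1, got {n}")
    if n == 1:
        return 0.0
    r_phi = integrate.quad(
        lambda t: 2.0 * math.sin(t) * math.cos(t) * _unpolarized_fresnel(t, n),
        0.0, math.pi / 2.0, limit=400,
    )[0]
    r_j = integrate.quad(
        lambda t: 3.0 * math.sin(t) * math.cos(t) ** 2 * _unpolarized_fresnel(t, n),
        0.0, math.pi / 2.0, limit=400,
    )[0]
    return (r_phi + r_j) / (2.0 - r_phi + r_j)


def effective_reflection(n: float, method: str = "polynomial") -> float:
    """Effective (internal) reflection coefficient of the tissue surface.

    ``method="polynomial"`` evaluates a Chebyshev fit valid for n in
    [1, 1.6] (max abs error 4.1e-4); ``method="integral"`` integrates the
    Fresnel reflectance numerically and works for any n >= 1.
    """
    if n < 1:
        raise ValueError(f"refractive index ratio must be >= 1, got {n}")
    if method == "integral":
        return fresnel_reflection_integral(n)
    if method != "polynomial":
        raise ValueError(f"unknown method {method!r}")
    if n == 1.0:
        return 0.0
    if n > 1.6:
        # polynomial fit domain ends at 1.6; fall back to the exact integral
        return fresnel_reflection_integral(n)
    return float(max(_REFF_CHEB(n), 0.0))


@dataclass(frozen=True)
class SemiInfiniteGeometry:
    """Extrapolated-boundary image-source geometry for a half-space medium.

    ``rho`` is the source-detector separation on the surface, ``z0 = 1/musp``
    the depth of the effective isotropic source, ``zb`` the extrapolated
    boundary distance; ``r1`` and ``rb`` are the detector distances to the
    real and image sources.
    """

    rho: float
    z0: float
    zb: float
    reff: float
    r1: float = field(init=False)
    rb: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.rho > 0:
            raise ValueError(f"rho must be > 0, got {self.rho}")
        if not 0 <= self.reff < 1:
            raise ValueError(f"reff must be in [0, 1), got {self.reff}")
        object.__setattr__(self, "r1", math.hypot(self.rho, self.z0))
        object.__setattr__(self, "rb", math.hypot(self.rho, self.z0 + 2.0 * self.zb))
        if self.r1 == 0:
            raise ValueError("degenerate geometry: detector coincides with source")

    @classmethod
    def for_separation(
        cls, rho: float, optics: OpticalProperties, reff_method: str = "polynomial"
    ) -> "SemiInfiniteGeometry":
        """Build the geometry at separation ``rho`` (mm) from tissue optics."""
        reff = effective_reflection(optics.n, method=reff_method)
        z0 = 1.0 / optics.musp
        zb = (2.0 / 3.0) * (1.0 + reff) / ((1.0 - reff) * optics.musp)
        return cls(rho=rho, z0=z0, zb=zb, reff=reff)


def _decay_rate(optics: OpticalProperties, flow: FlowParams, tau):
    """K(tau) = sqrt(3 mua musp + 6 musp^2 k0^2 alpha_db tau), 1/mm."""
    k0 = wavenumber(optics)
    return np.sqrt(
        3.0 * optics.mua * optics.musp
        + 6.0 * optics.musp**2 * k0**2 * flow.alpha_db * np.asarray(tau, dtype=float)
    )


def g1_semi_infinite(
    optics: OpticalProperties,
    flow: FlowParams,
    geom: SemiInfiniteGeometry,
    tau,
):
    """Normalized field autocorrelation g1(rho, tau) in (0, 1].

    g1 = G1(rho, tau) / G1(rho, 0) with
    G1 = (3 musp / 4 pi) [exp(-K r1)/r1 - exp(-K rb)/rb]; the 3 musp / 4 pi
    prefactor cancels in the normalization.  Accepts scalar or array ``tau``
    (s); monotone non-increasing in tau, identically 1 for a static medium.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")

    def _g1_unnorm(t):
        k = _decay_rate(optics, flow, t)
        return np.exp(-k * geom.r1) / geom.r1 - np.exp(-k * geom.rb) / geom.rb

    out = _g1_unnorm(tau) / _g1_unnorm(0.0)
    return out if out.ndim else float(out)


def exposure_integrated_contrast(
    g1,
    exposure: float,
    beta: float = 1.0,
    *,
    rtol: float = 1e-10,
) -> float:
    """kappa^2 = (2 beta / T) int_0^T (1 - tau/T) g1(tau)^2 dtau.

    ``g1`` is any callable of lag time (s).  For stiff kernels that collapse
    at tau << T the integration interval is truncated where g1^2 falls below
    1e-14 (the discarded tail is bounded by 1e-14 * T).  Raises
    ``RuntimeError`` if the quadrature does not converge.
    """
    if not exposure > 0:
        raise ValueError(f"exposure must be > 0, got {exposure}")
    upper = exposure
    if float(g1(exposure)) ** 2 < 1e-14:
        lo, hi = 0.0, exposure
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            if float(g1(mid)) ** 2 < 1e-14:
                hi = mid
            else:
                lo = mid
        upper = hi
    val, err, *rest = integrate.quad(
        lambda t: (1.0 - t / exposure) * float(g1(t)) ** 2,
        0.0,
        upper,
        epsabs=0.0,
        epsrel=rtol,
        limit=500,
        full_output=1,
    )
    if len(rest) > 1:  # quad appended a convergence message
        raise RuntimeError(f"contrast quadrature did not converge: {rest[1]}")
    if val > 0 and err > 1e-6 * val:
        raise RuntimeError(
            f"contrast quadrature error {err:.3e} exceeds tolerance (value {val:.3e})"
        )
    return 2.0 * beta / exposure * val


def speckle_contrast_sq(
    optics: OpticalProperties,
    flow: FlowParams,
    geom: SemiInfiniteGeometry,
    exposure: float,
    beta: float | None = None,
) -> float:
    """Exposure-integrated squared speckle contrast kappa^2(rho, T).

    ``beta`` defaults to ``flow.beta``.  Bounded by (0, beta]; the bound is
    approached as T -> 0 and for a static medium (alpha_db = 0) it is exact.
    """
    b = flow.beta if beta is None else beta
    if flow.alpha_db == 0.0:
        return b  # g1 == 1: (2/T) int (1 - tau/T) dtau = 1 exactly
    return exposure_integrated_contrast(
        lambda t: g1_semi_infinite(optics, flow, geom, t), exposure, b
    )


def contrast_vs_flow_curve(
    optics: OpticalProperties,
    geom: SemiInfiniteGeometry,
    exposure: float,
    beta: float,
    alpha_db_grid,
) -> pd.DataFrame:
    """Tabulate kappa^2 and 1/kappa^2 over a grid of flow indices.

    Returns a DataFrame with columns ``rho_mm, exposure_s, alpha_db,
    kappa_sq, inv_kappa_sq``.  In the diffusive regime 1/kappa^2 grows
    linearly with alpha_db, which is what makes 1/kappa^2 a usable
    blood-flow index.
    """
    alpha_db_grid = np.atleast_1d(np.asarray(alpha_db_grid, dtype=float))
    if np.any(alpha_db_grid <= 0):
        raise ValueError("alpha_db grid values must be > 0")
    kappa_sq = np.array(
        [
            speckle_contrast_sq(
                optics, FlowParams(alpha_db=a, beta=beta), geom, exposure
            )
            for a in alpha_db_grid
        ]
    )
    return pd.DataFrame(
        {
            "rho_mm": geom.rho,
            "exposure_s": exposure,
            "alpha_db": alpha_db_grid,
            "kappa_sq": kappa_sq,
            "inv_kappa_sq": 1.0 / kappa_sq,
        }
    )
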