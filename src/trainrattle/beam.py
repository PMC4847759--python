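"""Cantilever-beam mechanics of the feather rachis.

The rachis is treated as an Euler-Bernoulli cantilever of length ``L_R``
(clamped at the insertion, tip free or hinged), bending stiffness ``G' I``
(dynamic storage modulus times second moment of area) and feather linear
density ``mu_F``.  Resonant frequencies follow

    f_k = K_k^2 / (2 pi L_R^2) * sqrt(G' I / mu_F)

with ``K_k`` a root of the boundary's characteristic equation.  A heavy tip
ornament of mass ``M_E`` lowers every frequency by the lumped-tip-mass
correction ``1 / sqrt(1 + 4.1 M_E / M_F)``.

Cross-sections are modeled as a pith-filled cortex shell: a dense keratin
cortex annulus of thickness ``t`` around a light pith core.  ``t`` is not
measurable from the outside; it is recovered per segment by inverting the
measured linear density given the outer diameter and the two densities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .datatypes import Boundary, BucklingAssessment, RachisProfile

__all__ = [
    "characteristic_coefficient",
    "resonant_frequency",
    "resonant_frequency_with_tip_mass",
    "second_moment_profile",
    "i_over_mu_avg",
    "rescale_profile",
    "buckling_stresses",
    "fit_length_scaling",
    "ScalingFit",
    "TIP_MASS_COEFF",
]

# Lumped-correction coefficient for a point mass at the cantilever tip
# (ratio of tip mass to effective modal mass of the distributed beam).
TIP_MASS_COEFF = 4.1


def _char_clamped_free(K: float) -> float:
    return math.cos(K) * math.cosh(K) + 1.0


def _char_clamped_hinged(K: float) -> float:
    return math.tan(K) - math.tanh(K)


def characteristic_coefficient(
    boundary: Boundary | str, k: int, tol: float = 1e-10
) -> float:
    """k-th characteristic root ``K_k`` of the cantilever boundary condition.

    clamped-free: k-th positive root of ``cos K cosh K = -1``
    (K_1 = 1.8751, K_2 = 4.6941, ...).

    clamped-hinged: roots of ``tan K = tanh K`` (3.9266, 7.0686, 10.2102, ...),
    indexed so that mode ``k = 2`` maps to the first positive nonzero root.
    That convention matches how the hinged-tip model is used for feathers:
    a mode with k-1 nodes has one node pinned at the tip and k-2 interior
    ones, so the (k-1)-th hinged root drives mode k.  ``k = 1`` is therefore
    undefined for the hinged tip.

    Roots are located by bracketed bisection (``scipy.optimize.brentq``)
    within analytically known brackets, to absolute tolerance ``tol``.
    """
    boundary = Boundary(boundary)
    if k < 1:
        raise ValueError("mode index k must be >= 1")
    if boundary is Boundary.CLAMPED_FREE:
        # k-th root lies in ((k-1)pi, k pi); keep clear of the endpoints
        # where cosh blows up the function scale.
        j = k
        lo, hi = max((j - 1) * math.pi, 1e-6), j * math.pi
        return float(optimize.brentq(_char_clamped_free, lo, hi, xtol=tol))
    # clamped-hinged: j-th nonzero root lies in (j*pi, (j+1/2)*pi), within a
    # branch of tan; tan K > 1 ~ tanh K near the upper end.
    if k < 2:
        raise ValueError(
            "clamped_hinged roots are indexed from mode k = 2 (the tip node "
            "is one of the mode's k-1 nodes); k = 1 has no hinged-tip root"
        )
    j = k - 1
    lo, hi = j * math.pi + 1e-9, (j + 0.5) * math.pi - 1e-9
    return float(optimize.brentq(_char_clamped_hinged, lo, hi, xtol=tol))


def resonant_frequency(
    K_k: float, L_R: float, G_prime: float, I: float, mu_F: float
) -> float:
    """Resonant frequency (Hz) of mode ``K_k`` for a uniform cantilever.

    ``f_k = K_k^2 / (2 pi L_R^2) * sqrt(G' I / mu_F)``.
    """
    for name, v in (("K_k", K_k), ("L_R", L_R), ("G_prime", G_prime),
                    ("I", I), ("mu_F", mu_F)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    return K_k**2 / (2.0 * math.pi * L_R**2) * math.sqrt(G_prime * I / mu_F)


def resonant_frequency_with_tip_mass(
    K_k: float,
    L_R: float,
    G_prime: float,
    I_over_mu_avg: float,
    M_E: float,
    M_F: float,
) -> float:
    """Resonant frequency (Hz) including a lumped tip-ornament mass.

    ``f_k ~ K_k^2/(2 pi L_R^2) * sqrt(G' (I/mu_F)_avg / (1 + 4.1 M_E/M_F))``

    with ``M_E`` the ornament (eyespot) mass and ``M_F`` the mass of the rest
    of the feather.  Reduces to :func:`resonant_frequency` when ``M_E = 0``.
    """
    if M_F <= 0:
        raise ValueError("M_F must be positive")
    if M_E < 0:
        raise ValueError("M_E must be non-negative")
    base = resonant_frequency(K_k, L_R, G_prime, I_over_mu_avg, 1.0)
    return base / math.sqrt(1.0 + TIP_MASS_COEFF * M_E / M_F)


# ---------------------------------------------------------------------------
# Cross-section model: pith-filled cortex shell


def _ellipse_area(a: float, b: float) -> float:
    return math.pi * a * b


def _ellipse_I(a: float, b: float) -> float:
    """Second moment about the axis perpendicular to semi-axis ``a``
    (bending displacement along ``a``)."""
    return math.pi * a**3 * b / 4.0


def _segment_mu(t: float, a1: float, a2: float, rho_c: float, rho_p: float) -> float:
    """Linear density of a shell of thickness t around a pith core."""
    core = _ellipse_area(a1 - t, a2 - t)
    return rho_c * (_ellipse_area(a1, a2) - core) + rho_p * core


def solve_wall_thickness(
    D1: float,
    mu_R: float,
    cortex_density: float,
    pith_density: float,
    D2: float | None = None,
) -> float:
    """Invert the measured rachis linear density for cortex wall thickness.

    The section is an (elliptical) cortex shell of uniform thickness ``t``
    filled with pith.  ``mu_R(t)`` is strictly increasing on
    ``t in (0, min(D1, D2)/2]`` because the cortex is denser than the pith,
    so the root is unique when it exists.
    """
    if cortex_density <= pith_density or pith_density < 0:
        raise ValueError("require cortex_density > pith_density >= 0")
    a1 = D1 / 2.0
    a2 = (D2 if D2 is not None else D1) / 2.0
    t_max = min(a1, a2)
    mu_lo = _segment_mu(0.0, a1, a2, cortex_density, pith_density)
    mu_hi = _segment_mu(t_max, a1, a2, cortex_density, pith_density)
    if not (mu_lo < mu_R <= mu_hi * (1 + 1e-12)):
        raise InfeasibleSegmentError(
            f"mu_R={mu_R:.4g} kg/m outside feasible range "
            f"({mu_lo:.4g}, {mu_hi:.4g}] for D1={D1:.4g} m"
        )
    if mu_R >= mu_hi:
        return t_max
    f = lambda t: _segment_mu(t, a1, a2, cortex_density, pith_density) - mu_R
    return float(optimize.brentq(f, 0.0, t_max, xtol=1e-15))


class InfeasibleSegmentError(ValueError):
    """Measured linear density cannot be produced by any wall thickness."""


def second_moment_profile(
    profile: RachisProfile,
    cortex_density: float,
    pith_density: float,
    pith_modulus_ratio: float = 0.0,
) -> dict[str, np.ndarray]:
    """Second moment of area per segment from diameters and linear density.

    For each segment the cortex wall thickness ``t`` is recovered from
    ``mu_R`` (see :func:`solve_wall_thickness`); the bending second moment is
    the cortex annulus plus, optionally, a pith-core contribution scaled by
    ``pith_modulus_ratio`` (pith carries mass but negligible stiffness by
    default).

    Returns a dict with keys ``t`` (m), ``I_lateral`` and ``I_dorsoventral``
    (m^4) arrays over segments.
    """
    n = profile.x.size
    t = np.empty(n)
    I_lat = np.empty(n)
    I_dv = np.empty(n)
    D2 = profile.D2 if profile.D2 is not None else profile.D1
    for i in range(n):
        try:
            ti = solve_wall_thickness(
                profile.D1[i], profile.mu_R[i], cortex_density, pith_density,
                D2=D2[i],
            )
        except InfeasibleSegmentError as err:
            raise InfeasibleSegmentError(f"segment {i}: {err}") from err
        a1, a2 = profile.D1[i] / 2.0, D2[i] / 2.0
        core_lat = _ellipse_I(a1 - ti, a2 - ti)
        core_dv = _ellipse_I(a2 - ti, a1 - ti)
        t[i] = ti
        I_lat[i] = _ellipse_I(a1, a2) - core_lat + pith_modulus_ratio * core_lat
        I_dv[i] = _ellipse_I(a2, a1) - core_dv + pith_modulus_ratio * core_dv
    return {"t": t, "I_lateral": I_lat, "I_dorsoventral": I_dv}


def i_over_mu_avg(profile: RachisProfile, I: np.ndarray) -> float:
    """Length-weighted average of the ratio ``I(x) / mu_F(x)`` (m^4 / (kg/m))."""
    I = np.asarray(I, dtype=float)
    w = profile.dx
    return float(np.sum(w * I / profile.mu_F) / np.sum(w))


def rescale_profile(values: np.ndarray) -> np.ndarray:
    """Normalize a positional profile to value 1 at the base (first segment).

    Used to compare the functional form of ``I(u)`` or ``mu_R(u)`` across
    feathers of different size: profiles that differ only by a scale factor
    collapse onto one curve.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty profile")
    if values[0] == 0:
        raise ValueError("value at u=0 is zero; cannot rescale")
    return values / values[0]


def buckling_stresses(
    profile: RachisProfile,
    E: float,
    cortex_density: float,
    pith_density: float,
    local_coeff: float = 0.6,
) -> BucklingAssessment:
    """Critical stresses for Euler and local (shell-kinking) buckling.

    Per segment midpoint, with ``L_eff`` the distance from the segment to the
    tip and effective-length factor 2 (fixed-free column):

    * Euler:  ``sigma_E = pi^2 E I / (A_cortex (2 L_eff)^2)`` -- elastic
      bowing of the whole shaft; recoverable.
    * Local:  ``sigma_L = c E t / r`` -- kinking of the tube wall;
      irreversible.  A solid section (t = r) has no wall to kink and gets an
      infinite sentinel.

    The governing (lower) critical stress at each position indicates which
    failure comes first; ``min_margin_location`` is the position where that
    governing stress is smallest, i.e. the weakest point of the shaft.
    """
    if E <= 0:
        raise ValueError("E must be positive")
    sm = second_moment_profile(profile, cortex_density, pith_density)
    t, I = sm["t"], sm["I_lateral"]
    D2 = profile.D2 if profile.D2 is not None else profile.D1
    a1, a2 = profile.D1 / 2.0, D2 / 2.0
    r = 0.5 * (a1 + a2)
    A_cortex = np.pi * (a1 * a2 - (a1 - t) * (a2 - t))
    x_mid = profile.x + 0.5 * profile.dx
    L_eff = np.maximum(profile.L_R - x_mid, 0.5 * profile.dx[-1])
    sigma_E = np.pi**2 * E * I / (A_cortex * (2.0 * L_eff) ** 2)
    # sections whose pith core is thinner than ~1 nm are effectively solid:
    # there is no wall to kink, so local buckling gets an infinite sentinel
    with np.errstate(divide="ignore"):
        sigma_L = np.where(t >= r - 1e-9, np.inf, local_coeff * E * t / r)
    governing = np.minimum(sigma_E, sigma_L)
    loc = float(x_mid[int(np.argmin(governing))])
    return BucklingAssessment(
        x=x_mid, sigma_euler=sigma_E, sigma_local=sigma_L, min_margin_location=loc
    )


# ---------------------------------------------------------------------------
# Frequency-length scaling


@dataclass(frozen=True)
class ScalingFit:
    """Power-law fit ``f = a * L^-b`` from log-log least squares."""

    b: float
    b_ci: tuple[float, float]
    prefactor: float
    r_squared: float
    n: int

    def predict(self, L: np.ndarray) -> np.ndarray:
        return self.prefactor * np.asarray(L, dtype=float) ** (-self.b)


def fit_length_scaling(lengths, frequencies) -> ScalingFit:
    """Fit ``f_k ∝ L_R^-b`` by least squares on log10 axes.

    Returns the exponent ``b`` (positive for frequency decreasing with
    length) with a 95% confidence interval from the linear regression.
    """
    L = np.asarray(lengths, dtype=float)
    f = np.asarray(frequencies, dtype=float)
    if L.size != f.size:
        raise ValueError("lengths and frequencies must match")
    if L.size < 3:
        raise ValueError("need at least 3 points for a scaling fit")
    if np.any(L <= 0) or np.any(f <= 0):
        raise ValueError("lengths and frequencies must be positive")
    X = np.log10(L)
    Y = np.log10(f)
    slope, intercept = np.polyfit(X, Y, 1)
    resid = Y - (slope * X + intercept)
    dof = L.size - 2
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((Y - Y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    sxx = float(np.sum((X - X.mean()) ** 2))
    if dof > 0 and sxx > 0:
        se = math.sqrt(ss_res / dof / sxx)
        from scipy import stats

        tcrit = stats.t.ppf(0.975, dof)
        half = tcrit * se
    else:
        half = 0.0
    b = -slope
    return ScalingFit(
        b=float(b),
        b_ci=(float(b - half), float(b + half)),
        prefactor=float(10.0**intercept),
        r_squared=float(min(max(r2, 0.0), 1.0)),
        n=int(L.size),
    )
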