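"""Closed-form advection-diffusion release model with an absorbing interface.

The drug-polymer matrix occupies the half-space z >= 0 with the release
interface at z = 0.  The density of states rho(z, t) obeys

    d(rho)/dt = D d2(rho)/dz2 + V d(rho)/dz,          z > 0, t > 0

i.e. uniform drift at speed V *toward* the interface plus diffusion with
coefficient D, with

    rho(z, 0) = rho0        (uniform initial loading)
    rho(0, t) = 0           (absorbing boundary: released drug is removed)
    rho(z, t) -> rho0       as z -> inf at any finite t.

The substitution rho = n * exp(-V z / (2 D) - V^2 t / (4 D)) reduces the
problem to the heat equation for n.  The absorbing boundary is enforced by
the method of images: n is extended to z < 0 as an odd function, and the
solution is the heat-kernel convolution of that extended initial data.
Carrying out the convolution gives the closed forms implemented here:

    rho(z, t) = (rho0 / 2) [ erfc(-(z + V t) / s)
                             - exp(-V z / D) erfc((z - V t) / s) ],
    s = sqrt(4 D t)

and the release rate (Fickian flux magnitude at z = 0)

    I(t) = rho0 [ (V / 2) (1 + erf x) + sqrt(D / (pi t)) exp(-x^2) ],
    x = sqrt(V^2 t / (4 D)).

I(t) diverges like t^(-1/2) as t -> 0+ (the initial concentration gradient
at the interface is infinite) and saturates at rho0 * V as t -> inf.  The
crossover between the diffusion-dominated and drift-dominated regimes is
the characteristic time t_e = 4 D / V^2.  At V = 0 everything collapses to
the textbook half-space diffusion solution rho = rho0 erf(z / s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.special import erf, erfc

from .errors import DomainError, NoFiniteAdvectiveTimescale, ValidationError

__all__ = [
    "TransportParams",
    "SpaceTimePoint",
    "ReleaseCurve",
    "characteristic_time",
    "initial_condition_extended",
    "transform_to_physical",
    "greens_convolution_density",
    "density_profile",
    "release_rate",
    "release_rate_short_time",
    "cumulative_release",
    "cumulative_release_exact",
]


@dataclass(frozen=True)
class TransportParams:
    """Transport parameters of the release model.

    V : drift speed toward the release interface (length/hour, >= 0)
    D : diffusion-type coefficient (length^2/hour, > 0)
    rho0 : initial uniform density of states in the matrix (> 0); also the
        amplitude of the transformed field at the interface.
    """

    V: float
    D: float
    rho0: float = 1.0

    def __post_init__(self):
        if not self.V >= 0:
            raise ValidationError(f"V must be >= 0, got {self.V}")
        if not self.D > 0:
            raise ValidationError(f"D must be > 0, got {self.D}")
        if not self.rho0 > 0:
            raise ValidationError(f"rho0 must be > 0, got {self.rho0}")


@dataclass(frozen=True)
class SpaceTimePoint:
    """Evaluation point; the closed forms are singular at t = 0."""

    z: float
    t: float

    def __post_init__(self):
        if not self.t > 0:
            raise DomainError(f"t must be > 0, got {self.t}")


@dataclass(frozen=True)
class ReleaseCurve:
    """Release rate and its running integral on a strictly increasing grid."""

    times: np.ndarray
    rate: np.ndarray
    cumulative: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        rate = np.asarray(self.rate, dtype=float)
        cumulative = np.asarray(self.cumulative, dtype=float)
        if times.ndim != 1 or np.any(np.diff(times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(rate < 0):
            raise ValidationError("rate must be >= 0 everywhere")
        if cumulative[0] < 0 or np.any(np.diff(cumulative) < 0):
            raise ValidationError("cumulative must be nonnegative and nondecreasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "rate", rate)
        object.__setattr__(self, "cumulative", cumulative)


def characteristic_time(params: TransportParams) -> float:
    """Crossover time t_e = 4 D / V^2 between diffusive and drift regimes."""
    if params.V == 0:
        raise NoFiniteAdvectiveTimescale(
            "V = 0: no finite advective time scale (short-time regime is global)"
        )
    return 4.0 * params.D / params.V**2


def initial_condition_extended(z, params: TransportParams):
    """Odd extension of the transformed initial data n(z, 0).

    In the physical region z > 0 the transformed field is
    n(z, 0) = rho0 * exp(+V z / (2 D)), so that
    rho(z, 0) = n(z, 0) * exp(-V z / (2 D)) = rho0.  For z < 0 the field is
    continued antisymmetrically, n(z, 0) = -n(-z, 0), which makes the
    heat-kernel convolution vanish at z = 0 for all time (absorbing
    boundary by the method of images).
    """
    z = np.asarray(z, dtype=float)
    magnitude = params.rho0 * np.exp(params.V * np.abs(z) / (2.0 * params.D))
    return np.sign(z) * magnitude


def transform_to_physical(n, z, t, params: TransportParams):
    """Map the transformed field n(z, t) back to the physical density rho."""
    z = np.asarray(z, dtype=float)
    return n * np.exp(-params.V * z / (2.0 * params.D) - params.V**2 * t / (4.0 * params.D))


def greens_convolution_density(
    p: SpaceTimePoint, params: TransportParams, quad_tol: float = 1e-10
) -> float:
    """Transformed density n(z, t) by numerical heat-kernel convolution.

    Evaluates (4 pi D t)^(-1/2) * Int n(z', 0) exp(-(z - z')^2 / (4 D t)) dz'
    over the extended axis.  Because n(z', 0) is an exponential times a
    sign, each half-line contributes an exact Gaussian integrand centered
    at z -/+ V t with width sqrt(2 D t); the integration window is truncated
    where the integrand falls below quad_tol.
    """
    if not quad_tol > 0:
        raise ValidationError("quad_tol must be > 0")
    V, D, rho0 = params.V, params.D, params.rho0
    z, t = p.z, p.t
    s2 = 4.0 * D * t

    def integrand(zp):
        return (
            np.sign(zp)
            * rho0
            * np.exp(V * np.abs(zp) / (2.0 * D) - (z - zp) ** 2 / s2)
            / np.sqrt(np.pi * s2)
        )

    # Each branch is a Gaussian centered at z +/- V t with peak log-height
    # C = V|z|/(2D) + V^2 t/(4D) (up to sign); truncate where it dips
    # below quad_tol.
    peak = V * abs(z) / (2.0 * D) + V**2 * t / (4.0 * D)
    log_floor = np.log(quad_tol * np.sqrt(np.pi * s2) / rho0)
    half_width = np.sqrt(s2 * max(1.0, peak - log_floor))
    lo = min(z - V * t, z + V * t, 0.0) - half_width
    hi = max(z - V * t, z + V * t, 0.0) + half_width
    val, _ = integrate.quad(
        integrand, lo, hi, points=[0.0], epsabs=quad_tol, epsrel=1e-12, limit=200
    )
    return val


def _as_positive_time(t):
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise DomainError("t must be > 0")
    return t


def density_profile(p: SpaceTimePoint, params: TransportParams) -> float:
    """Physical density rho(z, t) from the closed-form image solution.

    Satisfies rho(0, t) = 0 and rho -> rho0 as z -> inf at fixed t; reduces
    to rho0 * erf(z / sqrt(4 D t)) at V = 0.
    """
    if p.z < 0:
        raise DomainError(f"z must be >= 0 in the physical region, got {p.z}")
    V, D, rho0 = params.V, params.D, params.rho0
    z, t = p.z, p.t
    s = np.sqrt(4.0 * D * t)
    with np.errstate(under="ignore"):
        term_in = erfc(-(z + V * t) / s)
        term_img = np.exp(-V * z / D) * erfc((z - V * t) / s)
    return 0.5 * rho0 * (term_in - term_img)


def release_rate(t, params: TransportParams):
    """Release rate I(t) = D d(rho)/dz at z = 0 (flux magnitude).

    I(t) = rho0 [ (V/2)(1 + erf x) + sqrt(D/(pi t)) exp(-x^2) ],
    x = sqrt(V^2 t / (4 D)).  Diverges as t -> 0+, saturates at rho0 V.
    """
    t = _as_positive_time(t)
    V, D, rho0 = params.V, params.D, params.rho0
    x = np.sqrt(V**2 * t / (4.0 * D))
    with np.errstate(under="ignore"):
        out = rho0 * (0.5 * V * (1.0 + erf(x)) + np.sqrt(D / (np.pi * t)) * np.exp(-(x**2)))
    return out if out.shape else float(out)


def release_rate_short_time(t, params: TransportParams):
    """Short-time (t << t_e) approximation I(t) ~ rho0 [sqrt(D/(pi t)) + V/2]."""
    t = _as_positive_time(t)
    out = params.rho0 * (np.sqrt(params.D / (np.pi * t)) + 0.5 * params.V)
    return out if out.shape else float(out)


def cumulative_release_exact(t, params: TransportParams, amplitude: float = 1.0):
    """Exact antiderivative of the release rate, scaled by ``amplitude``.

    M(t) = rho0 [ (V t / 2)(1 + erf x) + sqrt(D t / pi) exp(-x^2)
                  + (D / V) erf x ]        (x = sqrt(V^2 t / (4 D)))
    with the V -> 0 limit M(t) = 2 rho0 sqrt(D t / pi).
    """
    t = _as_positive_time(t)
    V, D, rho0 = params.V, params.D, params.rho0
    if V == 0:
        out = amplitude * rho0 * 2.0 * np.sqrt(D * t / np.pi)
    else:
        x = np.sqrt(V**2 * t / (4.0 * D))
        with np.errstate(under="ignore"):
            out = amplitude * rho0 * (
                0.5 * V * t * (1.0 + erf(x))
                + np.sqrt(D * t / np.pi) * np.exp(-(x**2))
                + (D / V) * erf(x)
            )
    return out if np.shape(out) else float(out)


def cumulative_release(t_grid, params: TransportParams, amplitude: float = 1.0) -> ReleaseCurve:
    """Cumulative release on a strictly increasing positive time grid.

    Integrates the release rate from 0 by adaptive quadrature; the
    integrable t^(-1/2) singularity at the origin is removed by the
    substitution t = u^2.  Values are in the units set by ``amplitude``
    (percent of drug content when amplitude carries the percent scale).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size == 0:
        raise ValidationError("t_grid must be a nonempty 1-D array")
    if np.any(t_grid <= 0) or np.any(np.diff(t_grid) <= 0):
        raise ValidationError("t_grid must be strictly increasing and > 0")
    if not amplitude > 0:
        raise ValidationError("amplitude must be > 0")

    def integrand_u(u):
        return 2.0 * u * release_rate(u * u, params)

    edges = np.sqrt(np.concatenate(([0.0], t_grid)))
    increments = np.empty(t_grid.size)
    for k in range(t_grid.size):
        val, _ = integrate.quad(integrand_u, edges[k], edges[k + 1], epsabs=1e-12, epsrel=1e-11)
        increments[k] = val
    cumulative = amplitude * np.cumsum(increments)
    return ReleaseCurve(t_grid, release_rate(t_grid, params), cumulative)
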