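"""Estimate (V, D, amplitude) of the release model from a cumulative profile.

The model cumulative curve is amplitude * M(t; V, D) with M the exact
antiderivative of the release rate (rho0 is absorbed into the amplitude:
the semi-infinite matrix holds unbounded total mass, so only the shape of
the release law is identifiable and the percent scale must be free).
Fitting is bounded nonlinear least squares on the percent residuals, with
multiple start points drawn log-uniformly inside the bounds from a seeded
generator; the best of n_starts is returned and the whole procedure is
deterministic given the seed.

A structural caveat: the model curve is exactly invariant under the
rescaling (V, D, A) -> (c V, c^2 D, A / c) for any c > 0 — the length
unit of the half-space is arbitrary, so a release curve determines only
two parameter combinations, the crossover time t_e = 4 D / V^2 and the
diffusive amplitude A * sqrt(D) (equivalently the saturation rate A * V).
Individual (V, D, A) values returned by the fit are therefore one
arbitrary point on a zero-residual ridge; compare fits through the
gauge-invariant properties on :class:`FitResult`, not the raw parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    IdentifiabilityWarning,
    InsufficientDataError,
    NumericalFailure,
    ValidationError,
)
from .model import TransportParams, cumulative_release_exact
from .pipeline import DissolutionProfile

__all__ = ["FitOptions", "FitResult", "fit_release_model", "model_curve"]

_GASTRIC_END_H = 2.0  # points beyond this are the intestinal stage


@dataclass(frozen=True)
class FitOptions:
    v_bounds: tuple = (0.0, 10.0)       # drift speed (1/h in fitted scale)
    d_bounds: tuple = (1e-4, 10.0)      # diffusion coefficient
    a_bounds: tuple = (1e-2, 1e4)       # percent-scale amplitude
    n_starts: int = 16
    seed: int = 0
    xtol: float = 1e-12
    ftol: float = 1e-12
    gtol: float = 1e-12

    def __post_init__(self):
        if self.n_starts < 1:
            raise ValidationError("n_starts must be >= 1")
        for name, (lo, hi) in (("v", self.v_bounds), ("d", self.d_bounds),
                               ("a", self.a_bounds)):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValidationError(f"{name}_bounds must be finite and ordered")
        if self.d_bounds[0] <= 0 or self.a_bounds[0] <= 0 or self.v_bounds[0] < 0:
            raise ValidationError("bounds must respect V >= 0, D > 0, amplitude > 0")


@dataclass(frozen=True)
class FitResult:
    V: float
    D: float
    amplitude: float
    rss: float
    r_squared: float
    converged: bool
    n_starts_used: int
    seed: int

    def params(self) -> TransportParams:
        return TransportParams(V=self.V, D=self.D, rho0=1.0)

    @property
    def characteristic_time(self) -> float:
        """Gauge-invariant crossover time t_e = 4 D / V^2 (inf when V = 0)."""
        return 4.0 * self.D / self.V**2 if self.V > 0 else np.inf

    @property
    def saturation_rate(self) -> float:
        """Gauge-invariant long-time release slope A * V (percent/hour)."""
        return self.amplitude * self.V

    @property
    def diffusive_amplitude(self) -> float:
        """Gauge-invariant short-time scale A * sqrt(D); the early-time
        cumulative release is 2 * A * sqrt(D t / pi)."""
        return self.amplitude * np.sqrt(self.D)

    def to_dict(self) -> dict:
        return {
            "V": self.V, "D": self.D, "amplitude": self.amplitude,
            "rss": self.rss, "r_squared": self.r_squared,
            "converged": self.converged, "n_starts_used": self.n_starts_used,
            "seed": self.seed,
        }


def model_curve(t, V: float, D: float, amplitude: float):
    """Cumulative percent released at times t under the fitted model."""
    return cumulative_release_exact(t, TransportParams(V=V, D=D, rho0=1.0), amplitude)


def _start_points(opts: FitOptions) -> np.ndarray:
    rng = np.random.default_rng(opts.seed)
    v_lo = max(opts.v_bounds[0], 1e-3)  # log-uniform needs a positive floor
    los = np.log([v_lo, opts.d_bounds[0], opts.a_bounds[0]])
    his = np.log([opts.v_bounds[1], opts.d_bounds[1], opts.a_bounds[1]])
    return np.exp(rng.uniform(los, his, size=(opts.n_starts, 3)))


def fit_release_model(p: DissolutionProfile, opts: FitOptions = FitOptions()) -> FitResult:
    """Multi-start bounded least squares on percent residuals."""
    t = np.asarray(p.times_h, dtype=float)
    y = np.asarray(p.cumulative_pct, dtype=float)
    if t.size < 4:
        raise InsufficientDataError(
            f"need >= 4 time points to fit (V, D, amplitude); got {t.size}"
        )
    if np.any(t <= 0):
        raise ValidationError("all times must be > 0")
    n_intestinal = int(np.sum(t > _GASTRIC_END_H))
    if n_intestinal <= 3:
        warnings.warn(
            f"only {n_intestinal} points beyond {_GASTRIC_END_H} h: the (V, D, "
            "amplitude) surface is nearly flat along compensating directions "
            "on short horizons; estimates may be unreliable",
            IdentifiabilityWarning,
            stacklevel=2,
        )

    lo = np.array([opts.v_bounds[0], opts.d_bounds[0], opts.a_bounds[0]])
    hi = np.array([opts.v_bounds[1], opts.d_bounds[1], opts.a_bounds[1]])

    def residuals(theta):
        return model_curve(t, *theta) - y

    best = None
    n_used = 0
    for x0 in _start_points(opts):
        n_used += 1
        try:
            res = least_squares(
                residuals, np.clip(x0, lo, hi), bounds=(lo, hi),
                xtol=opts.xtol, ftol=opts.ftol, gtol=opts.gtol,
            )
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0]:
            best = (rss, res)
    if best is None:
        raise NumericalFailure(
            f"all {n_used} starts failed to converge (n={t.size} points, "
            f"t in [{t[0]:g}, {t[-1]:g}] h)"
        )
    rss, res = best
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else -np.inf)
    V_hat, D_hat, A_hat = (float(v) for v in res.x)
    return FitResult(
        V=V_hat, D=D_hat, amplitude=A_hat, rss=rss, r_squared=r2,
        converged=bool(res.success), n_starts_used=n_used, seed=opts.seed,
    )
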