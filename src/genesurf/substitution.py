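"""Substitution rate of recurrent beneficial mutations at the front.

New mutations arise proportionally to the local wildtype density N*c0(x)
and fix with the surfing probability u(x); the normalized substitution
rate is the tradeoff integral

    phi = N * integral( c0(x) * u(x) dx ),

normalized so that neutral mutations give phi = 1 (substitution rate equals
mutation rate: exactly one extant lineage fixes at the front).  The
substitution rate per unit time is Lambda = mu * phi.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .branching import solve_surfing_bvp
from .core import WaveProfile, average_profile
from .params import ModelParams
from .surfing import surfing_curve

ROUTE_BVP = "BVP"
ROUTE_MONTE_CARLO = "MONTE_CARLO"
#: below this fitness ratio b/a the linearized branching theory is outside
#: its validity range and the Monte-Carlo route is used instead
BVP_MIN_GAMMA = 1.2


@dataclass
class SubstitutionResult:
    params: ModelParams
    phi: float
    lam: float          # Lambda = mu * phi
    route: str
    se: float = float("nan")
    error: str | None = None
    meta: dict = field(default_factory=dict)


def phi_from_curves(profile: WaveProfile, u: np.ndarray, N: int,
                    u_se: np.ndarray | None = None,
                    edge_frac: float = 0.1, edge_tol: float = 0.01
                    ) -> tuple[float, float]:
    """Trapezoidal tradeoff integral phi = N * sum c0*u*dx on a shared grid.

    ``u`` must live on ``profile.x``.  The outermost ``edge_frac`` of the
    grid span on each side must contribute less than ``edge_tol`` of the
    integral, otherwise the window is too narrow and an error is raised.
    Returns ``(phi, se)``; the standard error propagates the binomial
    uncertainty of a Monte-Carlo u when ``u_se`` is given.
    """
    x = np.asarray(profile.x, dtype=float)
    u = np.asarray(u, dtype=float)
    if u.shape != x.shape:
        raise ValueError("u and profile must share one grid "
                         f"(got {u.shape} vs {x.shape})")
    integrand = profile.c0 * u
    total = float(np.trapezoid(integrand, x))
    if total > 0.0:
        cum = np.concatenate(([0.0], cumulative_trapezoid(integrand, x)))
        span = x[-1] - x[0]
        left = float(np.interp(x[0] + edge_frac * span, x, cum))
        right = total - float(np.interp(x[-1] - edge_frac * span, x, cum))
        if left > edge_tol * total or right > edge_tol * total:
            raise ValueError(
                "integral not converged within the window "
                f"(edge contributions {left / total:.1%} / "
                f"{right / total:.1%}); widen the grid")
    phi = N * total
    se = float("nan")
    if u_se is not None:
        w = np.gradient(x)           # trapezoid weights (dx at ends halved)
        w[0] *= 0.5
        w[-1] *= 0.5
        se = N * float(np.sqrt(np.sum((w * profile.c0 * u_se) ** 2)))
    return phi, se


def phi_monte_carlo(params: ModelParams, x_grid=None, n_reps: int = 2000,
                    seed: int | None = None,
                    **curve_kwargs) -> SubstitutionResult:
    """phi from the occupancy-weighted Monte-Carlo surfing curve.

    Uses the joint estimate ``wu(x) = E[(nW/N) * 1_fixation]`` rather than
    the product of separately averaged occupancy and fixation probability:
    local occupancy and fixation are correlated (a tip deme that actually
    holds wildtype is locally *less* advanced than the mean profile
    suggests), and only the joint expectation obeys the neutral lineage
    sum rule phi = 1.  The factorized integral is what the BVP route
    computes; their difference shrinks with N_tilde.
    """
    if seed is None:
        seed = params.seed
    if x_grid is None:
        x_grid = np.arange(-21.0, 33.0 + 1e-9, 3.0)
    curve = surfing_curve(params, x_grid, n_reps, seed=seed + 1,
                          **curve_kwargs)
    ones = WaveProfile(x=curve.x, c0=np.ones_like(curve.x), v=float("nan"),
                       n_samples=0)
    phi, se = phi_from_curves(ones, curve.wu, params.N, u_se=curve.wu_se)
    return SubstitutionResult(params=params, phi=phi, lam=params.mu * phi,
                              route=ROUTE_MONTE_CARLO, se=se,
                              meta={"curve": curve})


def phi_bvp(params: ModelParams, profile: WaveProfile | None = None,
            seed: int | None = None,
            profile_kwargs: dict | None = None) -> SubstitutionResult:
    """phi from the branching-theory curve solved on the averaged profile."""
    if params.gamma < BVP_MIN_GAMMA:
        warnings.warn(
            f"b/a = {params.gamma:.3g} < {BVP_MIN_GAMMA}: the linearized "
            "branching theory degrades toward neutrality; treat this phi "
            "as an estimate and prefer the Monte-Carlo route")
    if seed is None:
        seed = params.seed
    if profile is None:
        profile = average_profile(params, seed=seed,
                                  **(profile_kwargs or {}))
    theory = solve_surfing_bvp(profile, params.b)
    u_on_profile = np.interp(profile.x, theory.x, theory.u_theory)
    phi, _ = phi_from_curves(profile, u_on_profile, params.N)
    return SubstitutionResult(params=params, phi=phi, lam=params.mu * phi,
                              route=ROUTE_BVP,
                              meta={"theory": theory, "profile": profile})


def phi_sweep(params_list, route: str = ROUTE_BVP, seed: int = 0,
              n_reps: int = 2000, x_grid=None) -> list[SubstitutionResult]:
    """phi for each parameter set; rows record their route and any failure.

    Entries with b/a below the BVP validity threshold are forced onto the
    Monte-Carlo route.  A failing entry is reported with its error message
    and the sweep continues.
    """
    results = []
    for k, params in enumerate(params_list):
        entry_seed = seed + 10007 * (k + 1)
        try:
            if route == ROUTE_BVP and params.gamma >= BVP_MIN_GAMMA:
                res = phi_bvp(params, seed=entry_seed)
            else:
                res = phi_monte_carlo(params, x_grid=x_grid, n_reps=n_reps,
                                      seed=entry_seed)
        except Exception as exc:  # noqa: BLE001 - sweep must continue
            res = SubstitutionResult(params=params, phi=float("nan"),
                                     lam=float("nan"), route=route,
                                     error=str(exc))
        results.append(res)
    return results
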