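"""Branching-process theory of the surfing probability.

A rare mutant clone in the wave is approximated by a branching random walk
with birth rate b and position-dependent death rate b*c0(x) in the frame
co-moving with the measured wildtype wave (speed v): the net growth rate
b*(1 - c0(x)) equals b far in the tip and vanishes in the saturated bulk.
Its non-extinction probability u(x) then satisfies the boundary-value
problem

    u'' - v u' + b (1 - c0(x)) u - u^2 = 0,
    u(-inf) = 0,    u(+inf) = u_inf = b,

(the -v advection is the apparent drift of a lab-frame diffuser seen from
the co-moving frame): a Fisher-Kolmogorov equation running in the -x
direction with a cut-off where the wildtype bulk suppresses the growth
rate.  Toward the bulk the solution decays like exp(v x), so mutants deep
in the saturated region have exponentially small surfing probability.  The saturation value
b is the classical gambler's-ruin (Haldane) establishment probability of a
lone mutant in empty territory, whose death/birth rate ratio is 1 - b
under the model's event rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded
from sklearn.isotonic import IsotonicRegression

from .core import WaveProfile

MAX_NEWTON_ITER = 200
NEWTON_TOL = 1e-10


@dataclass
class TheoryCurve:
    """Predicted surfing probability on a grid, plus solver diagnostics."""

    x: np.ndarray
    u_theory: np.ndarray
    v_used: float
    residual_norm: float
    meta: dict = field(default_factory=dict)


def survival_closed_form(n0: int, death_birth_ratio: float) -> float:
    """Non-extinction probability 1 - rho**n0 of a linear birth-death process.

    ``rho`` is the death/birth rate ratio; for a lone mutant in empty
    territory under the implemented rates rho = 1 - b, so the establishment
    probability of a single mutant is b.  Critical or subcritical processes
    (rho >= 1) die out almost surely.
    """
    if n0 < 0:
        raise ValueError("n0 must be non-negative")
    rho = death_birth_ratio
    if rho >= 1.0:
        return 0.0
    if rho < 0.0:
        raise ValueError("death/birth ratio must be non-negative")
    return 1.0 - rho ** n0


def smooth_profile(profile: WaveProfile, warn_threshold: float = 0.01
                   ) -> np.ndarray:
    """Monotone (non-increasing) isotonic regression of the averaged c0.

    Raw averaged profiles carry sampling noise that destabilizes the Newton
    solve; isotonic smoothing removes it without changing the shape.
    """
    c0 = np.asarray(profile.c0, dtype=float)
    rises = np.diff(c0)
    if rises.size and rises.max() > warn_threshold:
        warnings.warn("non-monotone c0 input (profile noise); "
                      "proceeding on an isotonic-regression smoothing")
    iso = IsotonicRegression(increasing=False, y_min=0.0, y_max=1.0)
    return iso.fit_transform(profile.x, c0)


def growth_rate_field(x, profile: WaveProfile, b: float,
                      c0_smooth: np.ndarray | None = None) -> np.ndarray:
    """Net mutant growth rate b*(1 - c0(x)) interpolated onto ``x``.

    Tends to b in the far tip (empty territory) and to 0 in the saturated
    bulk -- the cut-off of the equivalent Fisher-Kolmogorov equation.
    """
    c0 = profile.c0 if c0_smooth is None else c0_smooth
    c0x = np.interp(np.asarray(x, dtype=float), profile.x, c0,
                    left=1.0, right=0.0)
    return b * (1.0 - c0x)


def _newton(u, g, v, h, u_left, u_right):
    """Damped Newton iteration for the discretized BVP; u modified in place."""
    n = u.size

    def residual(uu):
        full = np.empty(n + 2)
        full[0], full[-1] = u_left, u_right
        full[1:-1] = uu
        return ((full[2:] - 2 * full[1:-1] + full[:-2]) / h ** 2
                - v * (full[2:] - full[:-2]) / (2 * h)
                + g * full[1:-1] - full[1:-1] ** 2)

    F = residual(u)
    for _ in range(MAX_NEWTON_ITER):
        ab = np.zeros((3, n))
        ab[0, 1:] = 1.0 / h ** 2 - v / (2 * h)      # superdiagonal
        ab[1, :] = -2.0 / h ** 2 + g - 2.0 * u      # diagonal
        ab[2, :-1] = 1.0 / h ** 2 + v / (2 * h)     # subdiagonal
        delta = solve_banded((1, 1), ab, -F)
        norm0 = np.linalg.norm(F)
        lam = 1.0
        while True:
            u_new = u + lam * delta
            F_new = residual(u_new)
            if np.linalg.norm(F_new) <= norm0 * (1.0 - 1e-4 * lam) or lam <= 1e-4:
                break
            lam *= 0.5
        u, F = u_new, F_new
        if np.max(np.abs(lam * delta)) < NEWTON_TOL:
            return u, float(np.max(np.abs(F))), True
    return u, float(np.max(np.abs(F))), False


def solve_surfing_bvp(profile: WaveProfile, b: float,
                      window: tuple[float, float] | None = None,
                      grid_spacing: float = 0.1,
                      v: float | None = None,
                      u_left: float = 0.0) -> TheoryCurve:
    """Solve the surfing-probability boundary-value problem.

    Second-order central differences on a uniform grid with damped Newton
    iteration; boundary conditions u = 0 deep in the bulk and u = b (the
    positive root of b*u - u^2) in the far tip.  ``v`` defaults to the
    measured finite-N wave speed stored in the profile, per the cut-off
    picture in which the mutant wave is slowed down to the actual wildtype
    speed.
    """
    if grid_spacing > 0.1:
        raise ValueError("grid spacing must be <= 0.1 deme")
    if v is None:
        v = profile.v
    if window is None:
        window = (float(profile.x[0]), float(profile.x[-1]))
    u_inf = b
    x = np.arange(window[0], window[1] + grid_spacing / 2, grid_spacing)
    c0s = smooth_profile(profile)
    g = growth_rate_field(x, profile, b, c0_smooth=c0s)
    # initial guess: a sigmoid centred on the Brunet-Derrida standoff
    # distance implied by the measured speed (fallback: centre of window)
    if v < 2.0 * np.sqrt(b):
        L_guess = np.pi / np.sqrt(2.0 * b * (1.0 - v / (2.0 * np.sqrt(b))))
    else:
        L_guess = 0.5 * (window[0] + window[1])
    u0 = u_inf * (1.0 + np.tanh((x[1:-1] - L_guess) / 4.0)) / 2.0
    u0 = np.maximum(u0, u_left)
    u, res, ok = _newton(u0, g[1:-1], v, grid_spacing, u_left, u_inf)
    if not ok:
        # pseudo-transient continuation, then retry Newton
        full = np.concatenate(([u_left], u, [u_inf]))
        tau = 0.2 * grid_spacing ** 2
        for _ in range(5000):
            lap = (full[2:] - 2 * full[1:-1] + full[:-2]) / grid_spacing ** 2
            adv = v * (full[2:] - full[:-2]) / (2 * grid_spacing)
            full[1:-1] += tau * (lap - adv + g[1:-1] * full[1:-1]
                                 - full[1:-1] ** 2)
        u, res, ok = _newton(full[1:-1], g[1:-1], v, grid_spacing, u_left,
                             u_inf)
        if not ok:
            raise RuntimeError(
                f"Newton iteration did not converge (residual {res:.3e})")
    u_full = np.concatenate(([u_left], u, [u_inf]))
    if u_full.min() < -1e-6 or u_full.max() > u_inf + 1e-9:
        raise RuntimeError("BVP solution violates 0 <= u <= u_inf bracketing")
    u_full = np.clip(u_full, 0.0, u_inf)  # shave numerical-zero undershoots
    return TheoryCurve(x=x, u_theory=u_full, v_used=float(v),
                       residual_norm=res,
                       meta={"b": b, "window": window,
                             "grid_spacing": grid_spacing})
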