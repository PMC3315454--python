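"""Analytic asymptotics for surfing onset and substitution rates.

Pure functions in deme units with diffusion constant 1.  The wildtype wave
is approximated by the exponential tip profile c0 = exp(-(v/2) x), the
surfing probability by a shifted exponential saturating at u_inf = b, and
the onset distance by matching the Brunet-Derrida cut-off speed of the
mutant "survival wave" (deterministic speed 2*sqrt(b)) to the wildtype
speed: the cut-off lowers a pulled front's speed by the classic
pi^2 / (2 (lambda L)^2) factor, so the standoff distance L is fixed by
speed equality.  The tradeoff integral of these approximations yields the
deterministic-limit and finite-N substitution rates; the leading behavior
of the deterministic branch is N * b * exp(-sqrt(a) L) / (sqrt(b) -
sqrt(a)), with an essential singularity at s -> 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

MODE_DET = "DET"
MODE_FINITE_N = "FINITE_N"


@dataclass(frozen=True)
class AsymptoticEstimates:
    a: float
    b: float
    N: int
    v_det_wt: float
    v_det_m: float
    lambda_wt: float
    L_det: float
    L_N: float
    phi_det: float
    phi_N: float
    Lc_heuristic: float


def exponential_approximations(a: float, b: float, v: float, L: float):
    """Exponential tip approximations (c0_approx(x), u_approx(x)).

    ``c0_approx(x) = min(1, exp(-(v/2) x))`` -- the linearized tip decay of
    the wildtype wave at its observed speed v (rate v/2 with D = 1);
    ``u_approx(x) = u_inf * min(1, exp(sqrt(b) (x - L)))`` with u_inf = b --
    the mutant survival wave rising with its own critical exponent sqrt(b)
    and saturating beyond the standoff distance L.
    """
    if v <= 0 or L <= 0 or b <= 0:
        raise ValueError("v, L and b must be positive")

    def c0_approx(x):
        return min(1.0, math.exp(-(v / 2.0) * x))

    def u_approx(x):
        return b * min(1.0, math.exp(math.sqrt(b) * (x - L)))

    return c0_approx, u_approx


def heuristic_Lc(a: float, b: float, N: int, v: float) -> float:
    """Heuristic onset distance (v/b) * ln(N_m / b), N_m = N / sqrt(b).

    Clone-size criterion: a clone starting at distance x grows at rate b
    until the wave arrives after time x/v, and fixes if by then it rivals
    the front population N_m of a mutant wave (occupancy N times the mutant
    front width 1/sqrt(b)); conditioning on survival divides the expected
    clone size by b.  An upper-bound-style estimate carrying a slowly
    varying O(1) prefactor.
    """
    if b <= 0 or N < 2 or v <= 0:
        raise ValueError("require b > 0, N >= 2, v > 0")
    arg = N / math.sqrt(b) / b
    if arg <= 1.0:
        warnings.warn("heuristic outside its regime (log argument <= 1)")
        return 0.0
    return (v / b) * math.log(arg)


def brunet_derrida_speed(v_det: float, decay_rate: float, L: float) -> float:
    """Pulled-front speed with growth cut off at distance L.

    v = v_det * (1 - pi^2 / (2 (decay_rate * L)^2)).
    """
    if L <= 0 or decay_rate <= 0:
        raise ValueError("L and decay_rate must be positive")
    v = v_det * (1.0 - math.pi ** 2 / (2.0 * (decay_rate * L) ** 2))
    if v <= 0:
        raise ValueError("cutoff too close for the asymptotic speed formula")
    return v


def lead_distance_deterministic(a: float, b: float) -> float:
    """Standoff distance L of the mutant survival wave, deterministic limit.

    Solves 2 sqrt(b) (1 - pi^2/(2 b L^2)) = 2 sqrt(a):
    L = pi / sqrt(2 b (1 - sqrt(a/b))); for small s this is ~ pi/sqrt(b s),
    the s^{-1/2} scaling of the surfing onset.
    """
    if b <= a:
        raise ValueError("deterministic lead distance requires b > a "
                         "(diverges in the neutral limit)")
    return math.pi / math.sqrt(2.0 * b * (1.0 - math.sqrt(a / b)))


def lead_distance_finite_N(a: float, b: float, N_tilde: float) -> float:
    """Standoff distance against the finite-N (Brunet-Derrida) wildtype speed.

    The wildtype wave itself is slowed to
    v_N = 2 sqrt(a) (1 - pi^2 / (2 ln^2 N_tilde)); matching the mutant
    cut-off speed to v_N gives L.  In the quasi-neutral limit b -> a this
    reduces to ln(N_tilde)/sqrt(a), the cutoff position of a noisy Fisher
    wave.
    """
    if N_tilde < 10:
        raise ValueError("N_tilde must be >= 10 for the cutoff asymptotics")
    if b < a:
        raise ValueError("requires b >= a")
    ln2 = math.log(N_tilde) ** 2
    v_N = 2.0 * math.sqrt(a) * (1.0 - math.pi ** 2 / (2.0 * ln2))
    if v_N <= 0:
        raise ValueError("N_tilde too small: finite-N wildtype speed <= 0")
    ratio = v_N / (2.0 * math.sqrt(b))
    return math.pi / math.sqrt(2.0 * b * (1.0 - ratio))


def _phi_integral(N: int, b: float, v: float, L: float) -> float:
    """Closed-form N * integral(c0_approx * u_approx dx) over the three regions.

    Bulk (x < 0, c0 = 1), intermediate (0 < x < L, both exponentials) and
    plateau (x > L, u = b).
    """
    sb = math.sqrt(b)
    k = sb - v / 2.0
    bulk = (b / sb) * math.exp(-sb * L)
    if abs(k) > 1e-12:
        mid = b * math.exp(-sb * L) * (math.expm1(k * L)) / k
    else:
        mid = b * math.exp(-sb * L) * L
    tip = b * (2.0 / v) * math.exp(-(v / 2.0) * L)
    return N * (bulk + mid + tip)


def phi_asymptotic(a: float, b: float, N: int, mode: str = MODE_DET) -> float:
    """Asymptotic normalized substitution rate from the exponential picture.

    ``DET`` uses the deterministic wildtype speed 2 sqrt(a) and standoff
    distance; ``FINITE_N`` uses the Brunet-Derrida-corrected speed and
    standoff for N_tilde = N sqrt(a).  Finite N shortens the standoff and
    softens the tip decay, strongly enhancing the rate.
    """
    if mode == MODE_DET:
        if b <= a:
            raise ValueError("DET mode requires b > a")
        v = 2.0 * math.sqrt(a)
        L = lead_distance_deterministic(a, b)
    elif mode == MODE_FINITE_N:
        N_tilde = N * math.sqrt(a)
        L = lead_distance_finite_N(a, b, N_tilde)
        ln2 = math.log(N_tilde) ** 2
        v = 2.0 * math.sqrt(a) * (1.0 - math.pi ** 2 / (2.0 * ln2))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return _phi_integral(N, b, v, L)


def estimates(a: float, b: float, N: int,
              v: float | None = None) -> AsymptoticEstimates:
    """Bundle of all asymptotic quantities for one parameter set."""
    v_wt = 2.0 * math.sqrt(a)
    v_obs = v_wt if v is None else v
    return AsymptoticEstimates(
        a=a, b=b, N=N,
        v_det_wt=v_wt,
        v_det_m=2.0 * math.sqrt(b),
        lambda_wt=v_obs / 2.0,
        L_det=lead_distance_deterministic(a, b) if b > a else float("inf"),
        L_N=lead_distance_finite_N(a, b, N * math.sqrt(a)),
        phi_det=phi_asymptotic(a, b, N, MODE_DET) if b > a else float("nan"),
        phi_N=phi_asymptotic(a, b, N, MODE_FINITE_N),
        Lc_heuristic=heuristic_Lc(a, b, N, v_obs),
    )
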