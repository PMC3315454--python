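"""Closed-form asymptotics: anchors, limits, monotonicity, singular behavior."""

import math

import numpy as np
import pytest

from genesurf.asymptotics import (MODE_DET, MODE_FINITE_N,
                                  brunet_derrida_speed,
                                  exponential_approximations, heuristic_Lc,
                                  lead_distance_deterministic,
                                  lead_distance_finite_N, phi_asymptotic)


def test_exponential_approximation_anchors():
    a, b, v, L = 0.25, 0.3, 1.0, 12.0
    c0, u = exponential_approximations(a, b, v, L)
    assert c0(0.0) == pytest.approx(1.0)
    assert c0(-5.0) == 1.0                      # clipped in the bulk
    assert c0(2.0 / v * math.log(10)) == pytest.approx(0.1)
    assert u(L) == pytest.approx(b)             # saturation at the standoff
    assert u(L + 5) == pytest.approx(b)
    # deterministic tip exponent: decay rate sqrt(a) at v = 2 sqrt(a)
    c0d, _ = exponential_approximations(a, b, 2 * math.sqrt(a), L)
    assert c0d(1.0) == pytest.approx(math.exp(-math.sqrt(a)))


def test_heuristic_Lc_scalings():
    a, b, N = 0.25, 0.3, 400
    base = heuristic_Lc(a, b, N, v=1.0)
    assert heuristic_Lc(a, b, N, v=2.0) == pytest.approx(2 * base)
    assert base > 0


def test_brunet_derrida_speed_values():
    assert brunet_derrida_speed(1.0, 1.0, math.pi) == pytest.approx(0.5)
    assert brunet_derrida_speed(1.0, 1.0, 1e9) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        brunet_derrida_speed(1.0, 1.0, 1.0)  # cutoff too close


def test_lead_distance_inverse_consistency():
    """Feeding the deterministic standoff back into the cutoff-speed formula
    recovers the wildtype speed exactly."""
    a, b = 0.2, 0.3
    L = lead_distance_deterministic(a, b)
    v = brunet_derrida_speed(2 * math.sqrt(b), math.sqrt(b), L)
    assert v == pytest.approx(2 * math.sqrt(a), abs=1e-12)


def test_lead_distance_small_s_limit():
    a = 0.25
    for s in (1e-3, 1e-4):
        b = a * (1 + s)
        L = lead_distance_deterministic(a, b)
        assert L * math.sqrt(b * s) / math.pi == pytest.approx(1.0, abs=2e-3)


def test_lead_distance_monotone_in_s():
    a = 0.25
    Ls = [lead_distance_deterministic(a, a * (1 + s))
          for s in (0.05, 0.1, 0.2, 0.4)]
    assert all(x > y for x, y in zip(Ls, Ls[1:]))


def test_lead_distance_neutral_limit_rejected():
    with pytest.raises(ValueError):
        lead_distance_deterministic(0.25, 0.25)


def test_lead_distance_finite_N_quasi_neutral():
    a = 0.25
    L = lead_distance_finite_N(a, a, math.exp(10.0))
    assert L == pytest.approx(10.0 / math.sqrt(a))
    assert L == pytest.approx(20.0)


def test_finite_N_below_deterministic_and_converging():
    a, b = 0.2, 0.3
    L_det = lead_distance_deterministic(a, b)
    gaps = [L_det - lead_distance_finite_N(a, b, nt)
            for nt in (1e2, 1e6, 1e14, 1e300)]
    assert all(g > 0 for g in gaps)          # always below the limit
    assert gaps == sorted(gaps, reverse=True)  # and converging to it
    assert lead_distance_finite_N(a, b, 1e300) == pytest.approx(L_det,
                                                                rel=1e-4)


def test_phi_det_essential_singularity():
    """phi_det vanishes faster than any power of s as s -> 0."""
    a, N = 0.25, 1000
    s_grid = [1e-1, 1e-2, 1e-3, 1e-4]
    for k in (1, 2, 5):
        vals = [phi_asymptotic(a, a * (1 + s), N, MODE_DET) * s ** -k
                for s in s_grid]
        assert all(x > y for x, y in zip(vals, vals[1:]))
        assert vals[-1] < vals[0] * 1e-6


def test_finite_N_enhancement():
    """Genetic drift (finite N) strongly enhances the substitution rate."""
    a, s = 0.25, 0.01
    b = a * (1 + s)
    for N_tilde in (1e2, 1e4, 1e6, 1e8):
        N = int(N_tilde / math.sqrt(a))
        assert (phi_asymptotic(a, b, N, MODE_FINITE_N)
                > phi_asymptotic(a, b, N, MODE_DET))


def test_finite_N_nontrivial_power_law():
    """log phi vs log N at small s: a slowly varying local exponent far
    below 1, i.e. a non-trivial, strongly sublinear power-law-like growth
    (a well-mixed population would have exponent 1)."""
    a, s = 0.25, 0.01
    b = a * (1 + s)
    Ns = np.logspace(2.5, 6, 8)   # N_tilde >~ 150: inside the cutoff regime
    logphi = np.log([phi_asymptotic(a, b, int(N), MODE_FINITE_N) for N in Ns])
    slopes = np.diff(logphi) / np.diff(np.log(Ns))
    assert np.all(slopes < 0.5)                   # far from linear in N
    assert np.all(np.abs(np.diff(slopes)) < 0.1)  # exponent varies slowly


def test_phi_det_requires_selection():
    with pytest.raises(ValueError):
        phi_asymptotic(0.25, 0.25, 100, MODE_DET)
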