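"""Surfing-probability experiments.

A single mutant is inserted at a chosen front-relative position into a
relaxed all-wildtype wave; the run then continues until one allele has
disappeared from the co-moving box.  Outcomes:

* ``FIXATION`` -- no wildtype remains in the box (the mutants own the front),
* ``FAILURE`` -- the mutants are gone from the box but at least one crossed
  the left boundary (the clone survived for a while but was left behind),
* ``DEATH`` -- the mutants disappeared before reaching the left boundary.

The surfing probability u(x) is the fraction of FIXATION outcomes among
non-censored replicates; FAILURE counts as non-fixation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .core import (DEFAULT_MARGIN, BoxState, WaveProfile, front_position,
                   init_wave, shift_box, simulate)
from .params import ModelParams

FIXATION = "FIXATION"
FAILURE = "FAILURE"
DEATH = "DEATH"
CENSORED = "CENSORED"

#: decorrelation time (model time units) run between the shared relaxed
#: state and each mutant insertion, so replicates see independent front
#: configurations.
PRE_INSERT_TIME = 10.0


@dataclass
class SurfingOutcome:
    label: str
    t_end: float
    #: wildtype occupancy fraction of the target deme just before insertion;
    #: weights lineage-sum estimates (a mutation arises in an existing
    #: individual, so the mutational input at x is proportional to nW(x))
    weight: float = float("nan")


@dataclass
class SurfingCurve:
    """Estimated surfing probability u(x) on a grid of insertion offsets.

    Besides the per-deme fixation probability ``u`` (uniform-deme
    insertion), the curve carries the occupancy-weighted product
    ``wu = E[(nW/N) * 1_fixation]`` and its SE.  ``wu`` is the Monte-Carlo
    estimate of c0(x) u(x) *including* the correlation between local
    occupancy and fixation, which the factorized product of separately
    averaged c0 and u misses; the neutral lineage sum rule
    ``N * sum wu dx = 1`` holds only for the joint quantity.
    """

    x: np.ndarray
    u: np.ndarray
    se: np.ndarray
    n_reps: np.ndarray
    wu: np.ndarray | None = None
    wu_se: np.ndarray | None = None
    features: dict | None = None
    counts: dict = field(default_factory=dict)  # per-x outcome tallies
    meta: dict = field(default_factory=dict)


def _target_deme(state: BoxState, params: ModelParams, x_offset: float) -> int:
    fp = front_position(state, params)
    target = int(round(fp + x_offset)) - state.offset
    if not 0 <= target < params.L:
        raise ValueError(
            f"insertion deme {target} outside box [0, {params.L}); "
            "enlarge the box or reduce |x_offset|")
    return target


def insert_mutant(state: BoxState, params: ModelParams,
                  x_offset: float) -> BoxState:
    """Convert one particle in the deme at ``front + x_offset`` into a mutant.

    A wildtype is converted when present, otherwise a vacancy, so the
    per-deme particle total is unchanged.  ``x_offset`` is rounded to the
    nearest deme (the model's spatial resolution).
    """
    target = _target_deme(state, params, x_offset)
    if state.nW[target] >= 1:
        state.nW[target] -= 1
        state.nM[target] += 1
    elif state.nW[target] + state.nM[target] < params.N:
        state.nM[target] += 1
    else:
        raise ValueError("target deme is saturated with mutants")
    return state


def classify_outcome(state: BoxState, capped: bool = False) -> SurfingOutcome:
    """Classify a terminated run from its final box state."""
    totW = state.total_wildtype()
    totM = state.total_mutants()
    if capped and totW > 0 and totM > 0:
        return SurfingOutcome(CENSORED, state.t)
    if totW == 0:
        return SurfingOutcome(FIXATION, state.t)
    if totM != 0:
        raise ValueError("run has not terminated: both alleles present")
    if state.mutants_crossed_left >= 1:
        return SurfingOutcome(FAILURE, state.t)
    return SurfingOutcome(DEATH, state.t)


def relax_wave(params: ModelParams, burn_in: float = 150.0,
               seed: int | None = None) -> BoxState:
    """Initialize and burn in an all-wildtype wave to a steady profile."""
    if seed is None:
        seed = params.seed
    state = init_wave(params)
    return simulate(state, params, burn_in, seed=seed)


#: spacing (time units) between base-state snapshots of the relaxed wave
BASE_SPACING = 30.0


def base_ensemble(params: ModelParams, burn_in: float = 150.0,
                  n_bases: int = 20, spacing: float = BASE_SPACING,
                  seed: int | None = None) -> list[BoxState]:
    """Snapshots of a relaxed wave to branch replicates from.

    The wave profile has slow internal modes (its shape relaxes
    diffusively), so replicates branched from a *single* relaxed state
    remain correlated well beyond the per-replicate decorrelation period
    and a lone base realization can bias a whole curve.  Spreading
    replicates over an ensemble of snapshots taken ``spacing`` time units
    apart samples the steady state instead.
    """
    state = relax_wave(params, burn_in=burn_in, seed=seed)
    bases = [state.copy()]
    for _ in range(n_bases - 1):
        simulate(state, params, spacing)
        bases.append(state.copy())
    return bases


def run_replicate(base_state: BoxState, params: ModelParams, x_offset: float,
                  seed: int, pre_insert: float = PRE_INSERT_TIME,
                  max_time: float | None = None,
                  margin: int = DEFAULT_MARGIN) -> SurfingOutcome:
    """One insertion experiment started from a copy of ``base_state``."""
    if max_time is None:
        max_time = 1e6 / params.a
    state = base_state.copy()
    state.mutants_crossed_left = 0
    _kernels.set_seed(seed)
    if pre_insert > 0:
        simulate(state, params, pre_insert, margin=margin)
    # recentre so the tip window can host far-tip insertions
    shift_box(state, params, margin=params.L)
    weight = state.nW[_target_deme(state, params, x_offset)] / params.N
    insert_mutant(state, params, x_offset)
    pa, pb = 1.0 - params.a, 1.0 - params.b
    check = max(1, int(0.25 * params.N * params.L))
    max_steps = int(max_time * params.N * params.L)
    totW, totM, crossed, shifted, n_steps = _kernels.run_to_outcome(
        _kernels.STATE, state.nW, state.nM, params.N, pa, pb, margin,
        params.L // 2, check, max_steps)
    state.mutants_crossed_left += int(crossed)
    state.offset += int(shifted)
    state.t += n_steps * params.dt
    out = classify_outcome(state, capped=(totW > 0 and totM > 0))
    out.weight = weight
    return out


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Independent 32-bit seeds for n replicates, reproducible from one master."""
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)


def surfing_outcomes(params: ModelParams, x_offset: float, n_reps: int,
                     seed: int | None = None,
                     base_state: BoxState | list[BoxState] | None = None,
                     burn_in: float = 150.0,
                     pre_insert: float = PRE_INSERT_TIME,
                     max_time: float | None = None) -> dict:
    """Outcome tallies over ``n_reps`` insertion replicates at one offset.

    ``base_state`` may be a single relaxed state or an ensemble of them
    (see :func:`base_ensemble`, the default); replicates are spread
    round-robin over the ensemble.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if seed is None:
        seed = params.seed
    if base_state is None:
        base_state = base_ensemble(params, burn_in=burn_in, seed=seed)
    bases = base_state if isinstance(base_state, list) else [base_state]
    counts = {FIXATION: 0, FAILURE: 0, DEATH: 0, CENSORED: 0}
    wu_sum = 0.0
    wu_sq = 0.0
    n_wu = 0
    for i, child in enumerate(_child_seeds(seed, n_reps)):
        out = run_replicate(bases[i % len(bases)], params, x_offset,
                            int(child), pre_insert=pre_insert,
                            max_time=max_time)
        counts[out.label] += 1
        if out.label != CENSORED:
            v = out.weight if out.label == FIXATION else 0.0
            wu_sum += v
            wu_sq += v * v
            n_wu += 1
    counts["wu_mean"] = wu_sum / n_wu if n_wu else float("nan")
    if n_wu > 1:
        var = max(wu_sq / n_wu - counts["wu_mean"] ** 2, 0.0)
        counts["wu_se"] = (var / n_wu) ** 0.5
    else:
        counts["wu_se"] = float("nan")
    return counts


def estimate_surfing_probability(params: ModelParams, x_offset: float,
                                 n_reps: int, seed: int | None = None,
                                 **kwargs) -> tuple[float, float]:
    """Monte-Carlo estimate (u_hat, se) of the surfing probability at one offset.

    ``u_hat`` is the FIXATION fraction among non-censored replicates with
    binomial standard error ``sqrt(u (1 - u) / n)``.
    """
    counts = surfing_outcomes(params, x_offset, n_reps, seed=seed, **kwargs)
    n = n_reps - counts[CENSORED]
    if n == 0:
        raise RuntimeError("all replicates censored")
    u = counts[FIXATION] / n
    return u, float(np.sqrt(u * (1.0 - u) / n))


def surfing_curve(params: ModelParams, x_grid, n_reps: int,
                  seed: int | None = None, burn_in: float = 150.0,
                  pre_insert: float = PRE_INSERT_TIME,
                  max_time: float | None = None) -> SurfingCurve:
    """Estimate u(x) on a grid of insertion offsets.

    The wave is relaxed once into an ensemble of base snapshots shared by
    all grid points; every replicate branches from one of them with its
    own random stream and a ``pre_insert`` decorrelation period.
    """
    x_grid = np.asarray(x_grid, dtype=float)
    if x_grid.size == 0:
        raise ValueError("x_grid is empty")
    if np.any(np.diff(x_grid) <= 0):
        raise ValueError("x_grid must be strictly increasing")
    if seed is None:
        seed = params.seed
    base = base_ensemble(params, burn_in=burn_in, seed=seed)
    u = np.empty_like(x_grid)
    se = np.empty_like(x_grid)
    wu = np.empty_like(x_grid)
    wu_se = np.empty_like(x_grid)
    nn = np.empty(x_grid.size, dtype=np.int64)
    counts = {}
    for k, x in enumerate(x_grid):
        c = surfing_outcomes(params, x, n_reps, seed=seed + 7919 * (k + 1),
                             base_state=base, pre_insert=pre_insert,
                             max_time=max_time)
        counts[float(x)] = c
        n = n_reps - c[CENSORED]
        u[k] = c[FIXATION] / n
        se[k] = np.sqrt(u[k] * (1 - u[k]) / n)
        wu[k] = c["wu_mean"]
        wu_se[k] = c["wu_se"]
        nn[k] = n
    return SurfingCurve(x=x_grid, u=u, se=se, n_reps=nn, wu=wu, wu_se=wu_se,
                        counts=counts,
                        meta={"params": params, "n_reps": n_reps,
                              "seed": seed, "burn_in": burn_in})


def _cross(xs: np.ndarray, ys: np.ndarray, level: float) -> float:
    """First upward crossing of ``level`` in ``ys`` (scanning left to right)."""
    for i in range(1, ys.size):
        if (ys[i - 1] < level) and (ys[i] >= level):
            f = (level - ys[i - 1]) / (ys[i] - ys[i - 1])
            return float(xs[i - 1] + f * (xs[i] - xs[i - 1]))
    raise ValueError(f"curve never crosses level {level}")


def extract_features(curve: SurfingCurve,
                     profile: WaveProfile) -> tuple[float, float, float]:
    """Plateau height, onset distance and rise width of a surfing curve.

    * ``u_inf``   -- mean of the last three grid points (they must agree
      pairwise within twice their pooled SE, else the grid is too short),
    * ``L_c``     -- interpolated x where u = u_inf / 2 minus interpolated x
      where c0 = 1/2 (a difference of positions, so the front-estimator
      convention cancels),
    * ``Delta``   -- x(u = 0.75 u_inf) - x(u = 0.25 u_inf), an admissible
      formalization of the rise width as the 25-75% quantile distance.
    """
    if curve.x.size < 4:
        raise ValueError("curve too short to detect a plateau")
    tail_u = curve.u[-3:]
    tail_se = curve.se[-3:]
    for i in range(3):
        for j in range(i + 1, 3):
            pooled = np.hypot(tail_se[i], tail_se[j])
            if abs(tail_u[i] - tail_u[j]) > 2 * pooled + 1e-12:
                raise ValueError("no plateau detected: widen the grid to the tip")
    u_inf = float(tail_u.mean())
    x_half_u = _cross(curve.x, curve.u, u_inf / 2.0)
    # c0 decreases in x; reuse the crossing helper on the reversed arrays
    x_half_c = _cross(-profile.x[::-1], profile.c0[::-1], 0.5)
    x_half_c = -x_half_c
    L_c = x_half_u - x_half_c
    delta = _cross(curve.x, curve.u, 0.75 * u_inf) - _cross(
        curve.x, curve.u, 0.25 * u_inf)
    features = {"u_inf": u_inf, "L_c": L_c, "Delta": delta}
    curve.features = features
    return u_inf, L_c, delta
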