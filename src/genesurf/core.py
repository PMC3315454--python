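"""Stepping-stone simulator of a range expansion in a co-moving box.

The population expands rightward as a noisy Fisher-KPP (FKPP) wave.  The
simulation keeps a box of ``L`` demes centred on the advancing front by
periodically dropping saturated demes on the left and appending empty ones
on the right.  Positions are bookkept in a fixed lab frame through the
``offset`` of the leftmost deme.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .params import ModelParams

DEFAULT_MARGIN = 10


@dataclass
class BoxState:
    """Per-deme particle counts in the co-moving box.

    ``nW[i]`` and ``nM[i]`` are wildtype / mutant counts in deme ``i``;
    vacancies are implicit (``N - nW - nM``).  ``offset`` is the lab-frame
    position of deme 0 and never decreases; ``t`` is elapsed model time;
    ``mutants_crossed_left`` counts mutants contained in demes dropped at
    the left edge.
    """

    nW: np.ndarray
    nM: np.ndarray
    offset: int = 0
    t: float = 0.0
    mutants_crossed_left: int = 0

    def copy(self) -> "BoxState":
        return BoxState(self.nW.copy(), self.nM.copy(), self.offset, self.t,
                        self.mutants_crossed_left)

    def total_wildtype(self) -> int:
        return int(self.nW.sum())

    def total_mutants(self) -> int:
        return int(self.nM.sum())


@dataclass
class WaveProfile:
    """Front-aligned mean wildtype occupancy of an all-wildtype wave.

    ``x`` is the front-relative position grid in deme units (positive
    toward the propagation direction, 0 at the interpolated half-occupancy
    point), ``c0`` the mean occupancy fraction, ``v`` the measured front
    speed and ``stderr`` the per-point standard error over snapshots.
    """

    x: np.ndarray
    c0: np.ndarray
    v: float
    n_samples: int
    stderr: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def init_wave(params: ModelParams) -> BoxState:
    """Initial condition: left half of the box saturated with wildtype."""
    L = params.L
    nW = np.zeros(L, dtype=np.int64)
    nW[: math.ceil(L / 2)] = params.N
    return BoxState(nW=nW, nM=np.zeros(L, dtype=np.int64))


def front_position(state: BoxState, params: ModelParams) -> float:
    """Lab-frame position where total occupancy crosses N/2, scanned from the right.

    Linear interpolation between deme centres (demes sit at integer
    positions ``offset + i``).  Raises if the box is all-full or all-empty,
    which signals a mis-sized box.
    """
    occ = state.nW + state.nM
    half = params.N / 2.0
    idx = np.nonzero(occ >= half)[0]
    if idx.size == 0:
        raise RuntimeError("no half-occupancy crossing: box is (nearly) empty")
    i = idx[-1]
    if i == occ.shape[0] - 1:
        raise RuntimeError("no half-occupancy crossing: box is full to the right edge")
    frac = (occ[i] - half) / (occ[i] - occ[i + 1])
    return float(state.offset + i + frac)


def shift_box(state: BoxState, params: ModelParams,
              margin: int = DEFAULT_MARGIN) -> BoxState:
    """Shift the box if the rightmost occupied deme is within ``margin`` of the edge.

    Drops the k leftmost demes (recentering the rightmost occupied deme at
    L // 2), appends k empty demes, advances ``offset`` and counts dropped
    mutants.  No-op when the precondition is not met.  Modifies ``state``
    in place and returns it.
    """
    occ = state.nW + state.nM
    nz = np.nonzero(occ)[0]
    if nz.size == 0:
        return state
    r = int(nz[-1])
    L = params.L
    if r < L - margin:
        return state
    k = r - L // 2
    if k <= 0:
        return state
    _, dm = _kernels.shift_left(state.nW, state.nM, k)
    state.mutants_crossed_left += int(dm)
    state.offset += k
    return state


def simulate(state: BoxState, params: ModelParams, duration: float,
             seed: int | None = None, margin: int = DEFAULT_MARGIN,
             check_interval: float = 0.5) -> BoxState:
    """Advance the box by ``duration`` model time units, shifting as needed.

    Uses numba's global random stream; pass ``seed`` to (re)seed it, or
    ``None`` to continue the current stream.  Modifies ``state`` in place
    and returns it.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if seed is not None:
        _kernels.set_seed(seed)
    n_total = int(round(duration * params.N * params.L))
    block = max(1, int(check_interval * params.N * params.L))
    pa, pb = 1.0 - params.a, 1.0 - params.b
    done = 0
    while done < n_total:
        n = min(block, n_total - done)
        _kernels.steps(_kernels.STATE, state.nW, state.nM, params.N, pa, pb, n)
        done += n
        shift_box(state, params, margin)
    state.t += duration
    return state


def measure_speed(trajectory: np.ndarray) -> float:
    """Least-squares front speed from a (time, position) trajectory.

    ``trajectory`` is an (n, 2) array of post-burn-in samples.  Requires at
    least 10 points.
    """
    traj = np.asarray(trajectory, dtype=float)
    if traj.ndim != 2 or traj.shape[1] != 2:
        raise ValueError("trajectory must be an (n, 2) array of (t, position)")
    if traj.shape[0] < 10:
        raise ValueError("need at least 10 trajectory points to fit a speed")
    slope, _ = np.polyfit(traj[:, 0], traj[:, 1], 1)
    return float(slope)


def front_trajectory(params: ModelParams, burn_in: float, duration: float,
                     sample_interval: float = 1.0, seed: int | None = 0,
                     state: BoxState | None = None) -> np.ndarray:
    """Run an all-wildtype wave and record (t, front position) after burn-in."""
    if state is None:
        state = init_wave(params)
    if burn_in > 0:
        simulate(state, params, burn_in, seed=seed)
        seed = None
    n = int(round(duration / sample_interval))
    out = np.empty((n, 2))
    for k in range(n):
        simulate(state, params, sample_interval, seed=seed)
        seed = None
        out[k, 0] = state.t
        out[k, 1] = front_position(state, params)
    return out


def average_profile(params: ModelParams, burn_in: float = 150.0,
                    n_snapshots: int = 500, snapshot_interval: float = 1.0,
                    seed: int = 0, x_min: float = -45.0, x_max: float = 55.0,
                    dx: float = 0.5, speed_duration: float = 0.0
                    ) -> WaveProfile:
    """Front-aligned mean occupancy profile c0(x) of an all-wildtype wave.

    Runs a single wave, takes ``n_snapshots`` snapshots separated by
    ``snapshot_interval`` time units after ``burn_in``, aligns each on its
    interpolated front position, resamples the occupancy fraction onto a
    fixed front-relative grid and averages.  The front speed ``v`` is the
    least-squares slope of the recorded front trajectory.

    The front position performs a random walk around its mean drift, so a
    slope fitted over a few hundred time units carries a few-percent
    error -- too much for the theory solve, whose standoff distance is
    very sensitive to v.  A positive ``speed_duration`` extends the run
    by that many time units (without snapshot overhead) and replaces v by
    the end-to-end displacement rate over the whole window, the maximum-
    likelihood drift estimator for a diffusing front.

    Demes to the left of the box are saturated and demes to the right are
    empty, so the resampling clamps to 1 and 0 beyond the box.
    """
    if dx > 0.5:
        raise ValueError("grid spacing must be <= 0.5 deme")
    meta: dict = {"params": params, "burn_in": burn_in,
                  "n_snapshots": n_snapshots,
                  "snapshot_interval": snapshot_interval, "seed": seed}
    if n_snapshots < 50:
        meta["warning"] = f"only {n_snapshots} snapshots; profile may be noisy"
        warnings.warn(meta["warning"])
    state = init_wave(params)
    simulate(state, params, burn_in, seed=seed)
    x = np.arange(x_min, x_max + dx / 2, dx)
    acc = np.zeros_like(x)
    acc2 = np.zeros_like(x)
    traj = np.empty((n_snapshots, 2))
    deme_idx = np.arange(params.L, dtype=float)
    for k in range(n_snapshots):
        simulate(state, params, snapshot_interval)
        fp = front_position(state, params)
        traj[k] = (state.t, fp)
        rel = deme_idx + state.offset - fp
        f = np.interp(x, rel, state.nW / params.N, left=1.0, right=0.0)
        acc += f
        acc2 += f * f
    c0 = acc / n_snapshots
    var = np.maximum(acc2 / n_snapshots - c0 ** 2, 0.0)
    stderr = np.sqrt(var / n_snapshots)
    v = measure_speed(traj)
    if speed_duration > 0:
        simulate(state, params, speed_duration)
        f1 = front_position(state, params)
        v = (f1 - traj[0, 1]) / (state.t - traj[0, 0])
        meta["speed_window"] = state.t - traj[0, 0]
    return WaveProfile(x=x, c0=c0, v=v, n_samples=n_snapshots, stderr=stderr,
                       meta=meta)
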