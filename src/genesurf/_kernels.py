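"""Numba kernels for the stepping-stone event loop.

One *elementary step* consists of one migration event followed by one
duplication event and advances model time by ``dt = 1/(N*L)``:

* migration -- a uniformly chosen adjacent deme pair; one uniformly chosen
  particle from each deme; the two particles are swapped.  This gives each
  particle a hop rate of ~1 per unit time per direction, i.e. a diffusion
  constant of 1 (up to the documented L/(L-1) factor).
* duplication -- a uniformly chosen deme; an ordered pair of distinct
  particles (i, j) chosen uniformly without replacement; j is replaced by a
  copy of i.  The replacement is accepted with probability 1 except when a
  vacancy is copied over a wildtype (accepted with probability 1-a, i.e. a
  wildtype death) or over a mutant (probability 1-b).  This yields net
  low-density per-capita growth rates a and b and symmetric mutant<->wildtype
  replacement (neutral drift in full demes).

Random numbers come from an inlined xorshift128+ generator (bounded draws
via the 32-bit multiply-shift map, bias < 2^-32) because the event loop is
RNG-bound.  The generator state lives in the module-level ``STATE`` array;
callers seed it through ``set_seed`` (single-threaded use only).
"""

import numpy as np
from numba import njit

# particle type codes
_W, _M, _V = 0, 1, 2

#: global RNG state (xorshift128+), seeded via set_seed
STATE = np.array([0x9E3779B97F4A7C15, 0xBF58476D1CE4E5B9], dtype=np.uint64)


@njit(cache=True)
def _seed_state(state, seed):
    # splitmix64 expansion of the integer seed into the xorshift state
    z = np.uint64(seed)
    for i in range(2):
        z = z + np.uint64(0x9E3779B97F4A7C15)
        w = z
        w = (w ^ (w >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        w = (w ^ (w >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        w = w ^ (w >> np.uint64(31))
        state[i] = w
    if state[0] == np.uint64(0) and state[1] == np.uint64(0):
        state[0] = np.uint64(1)


def set_seed(seed):
    """Seed the global event-loop RNG (deterministic, single stream)."""
    _seed_state(STATE, int(seed) & 0xFFFFFFFFFFFFFFFF)


@njit(cache=True, inline="always")
def _next(state):
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= s1 << np.uint64(23)
    s1 ^= s1 >> np.uint64(17)
    s1 ^= s0 ^ (s0 >> np.uint64(26))
    state[1] = s1
    return s0 + s1


@njit(cache=True, inline="always")
def _randint(state, n):
    """Uniform integer in [0, n) for n < 2**32."""
    x = _next(state) >> np.uint64(32)
    return np.int64((x * np.uint64(n)) >> np.uint64(32))


@njit(cache=True, inline="always")
def _uniform(state):
    return (_next(state) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def steps(state, nW, nM, N, pa, pb, n_steps):
    """Run ``n_steps`` elementary steps in place.

    ``pa = 1 - a`` and ``pb = 1 - b`` are the death-acceptance
    probabilities.  Returns the net change ``(dW, dM)`` of the box totals
    so that callers can maintain running counts cheaply.
    """
    L = nW.shape[0]
    dW = np.int64(0)
    dM = np.int64(0)
    for _ in range(n_steps):
        # --- migration ---
        if L > 1:
            j = _randint(state, L - 1)
            r1 = _randint(state, N)
            if r1 < nW[j]:
                t1 = _W
            elif r1 < nW[j] + nM[j]:
                t1 = _M
            else:
                t1 = _V
            r2 = _randint(state, N)
            if r2 < nW[j + 1]:
                t2 = _W
            elif r2 < nW[j + 1] + nM[j + 1]:
                t2 = _M
            else:
                t2 = _V
            if t1 != t2:
                if t1 == _W:
                    nW[j] -= 1
                    nW[j + 1] += 1
                elif t1 == _M:
                    nM[j] -= 1
                    nM[j + 1] += 1
                if t2 == _W:
                    nW[j + 1] -= 1
                    nW[j] += 1
                elif t2 == _M:
                    nM[j + 1] -= 1
                    nM[j] += 1
        # --- duplication ---
        i = _randint(state, L)
        w = nW[i]
        m = nM[i]
        r1 = _randint(state, N)
        if r1 < w:
            t1 = _W
            w2 = w - 1
            m2 = m
        elif r1 < w + m:
            t1 = _M
            w2 = w
            m2 = m - 1
        else:
            t1 = _V
            w2 = w
            m2 = m
        r2 = _randint(state, N - 1)
        if r2 < w2:
            t2 = _W
        elif r2 < w2 + m2:
            t2 = _M
        else:
            t2 = _V
        if t1 != t2:
            accept = True
            if t1 == _V:
                # vacancy copied over an individual = a death event
                if t2 == _W:
                    accept = _uniform(state) < pa
                else:
                    accept = _uniform(state) < pb
            if accept:
                if t2 == _W:
                    nW[i] -= 1
                    dW -= 1
                elif t2 == _M:
                    nM[i] -= 1
                    dM -= 1
                if t1 == _W:
                    nW[i] += 1
                    dW += 1
                elif t1 == _M:
                    nM[i] += 1
                    dM += 1
    return dW, dM


@njit(cache=True, inline="always")
def _rightmost_occupied(nW, nM):
    for i in range(nW.shape[0] - 1, -1, -1):
        if nW[i] + nM[i] > 0:
            return i
    return -1


@njit(cache=True)
def shift_left(nW, nM, k):
    """Drop the k leftmost demes, append k empty demes on the right.

    Returns (dropped wildtype count, dropped mutant count)."""
    L = nW.shape[0]
    dw = np.int64(0)
    dm = np.int64(0)
    for i in range(k):
        dw += nW[i]
        dm += nM[i]
    for i in range(L - k):
        nW[i] = nW[i + k]
        nM[i] = nM[i + k]
    for i in range(L - k, L):
        nW[i] = 0
        nM[i] = 0
    return dw, dm


@njit(cache=True)
def run_to_outcome(state, nW, nM, N, pa, pb, margin, recenter, check_steps,
                   max_steps):
    """Run the event loop until one allele is gone from the box.

    The box is shifted whenever the rightmost occupied deme comes within
    ``margin`` demes of the right edge, recentering it at index
    ``recenter``; mutants contained in dropped demes are counted as having
    crossed the left boundary.

    Returns ``(totW, totM, crossed, shifted, n_steps)`` where ``totW`` and
    ``totM`` are the final in-box totals, ``crossed`` is the number of
    mutants dropped on the left, ``shifted`` the total box displacement and
    ``n_steps`` the number of elementary steps executed.  Termination at
    ``n_steps == max_steps`` with both alleles present signals a censored
    run to the caller.
    """
    L = nW.shape[0]
    totW = np.int64(0)
    totM = np.int64(0)
    for i in range(L):
        totW += nW[i]
        totM += nM[i]
    crossed = np.int64(0)
    shifted = np.int64(0)
    n_steps = np.int64(0)
    while totW > 0 and totM > 0 and n_steps < max_steps:
        block = check_steps
        if max_steps - n_steps < block:
            block = max_steps - n_steps
        dW, dM = steps(state, nW, nM, N, pa, pb, block)
        totW += dW
        totM += dM
        n_steps += block
        r = _rightmost_occupied(nW, nM)
        if r >= L - margin:
            k = r - recenter
            if k > 0:
                dw, dm = shift_left(nW, nM, k)
                totW -= dw
                totM -= dm
                crossed += dm
                shifted += k
    return totW, totM, crossed, shifted, n_steps


@njit(cache=True)
def tagged_walks(state, N, L, n_tags, t_max, n_record):
    """Trajectories of tagged particles in a saturated all-wildtype box.

    The box is completely full of wildtype, so duplication events never
    change any deme occupancy nor move a particle between demes; spatial
    displacement comes from migration swaps only, which are simulated
    exactly as induced by the event loop: per elementary step a uniformly
    chosen adjacent pair exchanges one uniformly chosen particle from each
    deme.  Time advances by dt = 1/(N*L) per elementary step, exactly as in
    the full kernel.

    Each tag is identified by a (deme, slot) label with slot in [0, N); a
    migration event draws one slot uniformly in each of the two demes and
    swaps them, so a tag moves exactly with the 1/N probability the event
    loop induces, and tags sharing a deme stay distinct particles.

    Tags start evenly spread in the middle third of the box.  Returns an
    array of shape (n_record, n_tags) of deme positions sampled at times
    ``t_max * (k + 1) / n_record``.
    """
    pos = np.empty(n_tags, np.int64)
    slot = np.empty(n_tags, np.int64)
    for q in range(n_tags):
        pos[q] = L // 3 + (q * (L // 3)) // n_tags
        slot[q] = q % N
    out = np.empty((n_record, n_tags), np.int64)
    total_steps = int(t_max * N * L)
    rec_every = total_steps // n_record
    k = 0
    for step in range(total_steps):
        j = _randint(state, L - 1)
        r1 = _randint(state, N)
        r2 = _randint(state, N)
        for q in range(n_tags):
            if pos[q] == j and slot[q] == r1:
                pos[q] = j + 1
                slot[q] = r2
            elif pos[q] == j + 1 and slot[q] == r2:
                pos[q] = j
                slot[q] = r1
        if (step + 1) % rec_every == 0 and k < n_record:
            for q in range(n_tags):
                out[k, q] = pos[q]
            k += 1
    return out
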