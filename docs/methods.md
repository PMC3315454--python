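# Methods

## Model

`genesurf` simulates a two-allele stepping-stone model of a range
expansion in a linear habitat.  Space is a chain of demes, each holding
exactly `N` particles of three kinds: wildtype individuals, mutant
individuals and vacancies.  Vacancies make the local logistic growth
explicit — a deme with vacancies can still grow; a full deme can only
exchange one type for another.

The dynamics is a sequence of elementary steps, each consisting of

1. **migration** — a uniformly chosen adjacent deme pair; one uniformly
   chosen particle from each deme; the two are swapped;
2. **duplication** — a uniformly chosen deme; an ordered pair of distinct
   particles `(i, j)` drawn without replacement; `j` is replaced by a copy
   of `i`.  The replacement is accepted with probability 1 except when a
   vacancy is copied over a wildtype (probability `1 - a`; a wildtype
   death) or over a mutant (probability `1 - b`).

Each elementary step advances model time by `dt = 1/(N L)`, where `L` is
the number of demes in the simulation box.  This calibration gives every
particle a hop rate of ~1 per direction per unit time (diffusion constant
`D = 1`, verified by the tagged-particle test to within a few percent; the
exact hop rate is `L/(L-1)` because `L` demes have `L - 1` adjacent pairs,
negligible at the default `L >= 120`) and net low-density per-capita
growth rates `a` for wildtype and `b` for mutants.  Ordered-pair sampling
without replacement multiplies reaction rates by `N/(N-1)`; both
discretization factors are documented rather than corrected, since they
vanish for the parameter ranges used.  In full demes, mutant-over-wildtype
and wildtype-over-mutant replacements are equally likely, so the mutant
count is an unbiased Moran process: the mutation is beneficial only at the
front, neutral in the saturated bulk.

With these rates an all-wildtype population expands as a noisy FKPP wave
with deterministic (pulled) speed `2 sqrt(a)`; the measured speed lies
below that bound and increases with `N` (the Brunet–Derrida finite-N
slowdown).

## Co-moving box

The wave is initialized with the left half of the box saturated and
followed in a co-moving frame: when the rightmost occupied deme comes
within `margin = 10` demes of the right edge, the leftmost `k` demes are
dropped and `k` empty demes appended, recentering the rightmost occupied
deme at `L/2`.  That split leaves ~`L/2` demes of saturated bulk behind
the front (so clones that fall behind are detected crossing the left
boundary) and ~`L/2 - width` demes of empty tip ahead (so far-tip
insertions fit in the box).  Mutants contained in dropped demes are
counted as having crossed the left boundary.  The default box is `L = 300`
demes; most experiments here use `L = 120`–`160`, which keeps both windows
several times wider than any length scale in the problem (front width
`1/sqrt(a)`, onset distance `L_c`, diffusion range of a failing clone).

The front position is the lab-frame point where total occupancy crosses
`N/2`, linearly interpolated and scanned from the right; it is robust to
stray pioneers, and any monotone-equivalent front convention only shifts
positions by a constant that cancels in `L_c` (a difference of positions).

## Surfing experiments

A surfing replicate relaxes an all-wildtype wave (burn-in 120–150 time
units, several box lengths of travel) into an *ensemble* of 20 base
snapshots taken 30 time units apart; replicates are spread round-robin
over the ensemble, and each runs an independent random stream for a
further 10-unit decorrelation period before insertion.  The ensemble
matters: the wave profile has slow internal modes (its shape relaxes
diffusively, over ~width^2 time units), so replicates branched from a
single relaxed state stay correlated far beyond the per-replicate
decorrelation period and a lone base realization can shift a whole
curve by several binomial standard errors.  Each replicate then
converts one particle at `round(front + x)` into a mutant
(a wildtype where available, else a vacancy, keeping deme occupancy
fixed), and runs until one allele is gone from the box:

* **fixation** — no wildtype left in the box;
* **failure** — no mutant left, but at least one crossed the left edge;
* **death** — no mutant left and none ever crossed.

The surfing probability `u(x)` is the fixation fraction; failures count
as non-fixation (they are rare in the front-focused regime and their
frequency is recorded per run).  A safety cap of `1e6/a` time units marks
censored runs; none occur at the default geometry.  Binomial standard
errors `sqrt(u(1-u)/n)` accompany every estimate.

Curve features: the plateau `u_inf` is the mean of the last three grid
points (required to agree pairwise within twice their pooled SE); `L_c`
is the interpolated half-plateau position minus the half-occupancy
position of the averaged profile; the rise width `Delta` is the 25–75%
quantile distance, one admissible formalization of "the width over which
the curve rises" and labeled as such in outputs.

## Branching theory

For sufficiently beneficial mutants (`b/a >= 1.2`; closer to neutrality
the linearization is invalid and only Monte-Carlo is used) a young clone
is approximated by a branching random walk with birth rate ~1 and death
rate excess set by the local wildtype density: net growth
`g(x) = b (1 - c0(x))`, where `c0` is the front-aligned mean occupancy of
an all-wildtype wave.  Its survival probability solves

    u'' - v u' + b (1 - c0(x)) u - u^2 = 0,   u(-inf) = 0,  u(+inf) = b,

in the frame moving at the *measured* wave speed `v` (the `-v u'` term is
the apparent drift of a lab-frame diffuser in the co-moving frame).  The
nonlinear coefficient is fixed to 1 by requiring saturation at the
closed-form establishment probability of a lone mutant in empty
territory, `1 - (1-b)^1 = b` (gambler's ruin with death/birth ratio
`1 - b` under the implemented rates).  The equation is an FKPP wave
running in the `-x` direction whose growth is cut off inside the bulk;
the cutoff pins the rise of `u` at a standoff distance ahead of the
front, and toward the bulk the solution decays like `exp(v x)`.

Numerics: second-order central differences on a uniform grid (spacing
0.1 deme), the averaged profile first made monotone by isotonic
regression (sampling noise in `c0` otherwise destabilizes the iteration),
damped Newton from a `tanh` initial guess centred on the
Brunet–Derrida standoff implied by the measured speed, convergence at
max-norm update `< 1e-10`, with a pseudo-transient fallback before
failing.  The solve window defaults to the measured profile's extent
(bulk end at `c0 ~ 1`, tip end beyond the plateau); solutions are
bracketed in `[0, b]` and negative undershoots below `1e-6` are clipped
to zero as numerical zeros.

## Substitution rate

Recurrent beneficial mutations arise proportionally to the wildtype
density `N c0(x)` (the mutant density is negligible at arrival in the
rare-mutation regime) and fix with probability `u(x)`.  The normalized
substitution rate is the tradeoff integral `phi = N * int c0 u dx`
(trapezoidal), normalized so neutral mutations give `phi = 1` — exactly
one extant lineage becomes ancestor of the future front, so the
occupancy-weighted sum of neutral fixation probabilities is 1.  The rate
per unit time is `Lambda = mu * phi`.

The two routes to `phi` differ in how they treat fluctuations.  The BVP
route evaluates the factorized integral of the *mean* profile and the
theory curve — the mean-field expression.  The Monte-Carlo route instead
records, for every replicate, the wildtype occupancy of the target deme
just before insertion and integrates the joint estimate
`wu(x) = E[(nW/N) * 1_fixation]`.  The distinction matters: at a fixed
front offset, occupancy and fixation are anticorrelated (a tip deme that
actually holds wildtype marks a locally advanced front, so an individual
there is effectively *less* advanced than the mean profile suggests; the
mostly-empty demes that uniform insertion samples are effectively more
advanced).  Only the joint expectation obeys the neutral sum rule — the
factorized product overshoots it by tens of percent at `N_tilde ~ 20`,
and the gap closes as `N_tilde` grows.  An integral whose outer 10% of
the window contributes more than 1% on either side is refused as
unconverged.

## Asymptotics

Closed forms use the exponential approximations `c0 ~ exp(-(v/2) x)` and
`u ~ b exp(sqrt(b)(x - L))`: the cutoff formula
`v = v_det (1 - pi^2 / (2 (lambda L)^2))` for a pulled front, the
deterministic standoff `L = pi / sqrt(2 b (1 - sqrt(a/b)))` (~
`pi/sqrt(bs)` at small `s`), its finite-N counterpart against the slowed
wildtype speed at `N_tilde = N sqrt(a)` (reducing to `ln(N_tilde)/
sqrt(a)` in the quasi-neutral limit), and the three-region closed form of
the tradeoff integral.  The deterministic rate has an essential
singularity at `s -> 0`; any finite `N` enhances it strongly.  Prefactors
follow from direct evaluation of the integral and are exercised through
limits, monotonicity and the finite-N/deterministic ordering — the
oscillatory sub-structure of near-critical fronts is deliberately dropped
(leading order only).  The heuristic onset estimate
`L_c ~ (v/b) ln(N_m / b)` with `N_m = N/sqrt(b)` (clone must outgrow a
mutant front population before the wave arrives) is an upper-bound-style
estimate with a slowly varying O(1) prefactor.

## Control parameters and data collapse

Rescaling time by `a` and space by `sqrt(a)` in the Langevin limit of the
event rates leaves two control parameters: the relative fitness
`gamma = b/a` and the drift strength `N_tilde = N sqrt(a)` (the typical
occupancy of the wave nose).  The collapse test estimates surfing curves
for two raw parameter sets, rescales `x` by `sqrt(a)`, normalizes `u` by
its plateau `b`, and declares PASS when the pointwise discrepancy stays
within 3 pooled SE at >= 90% of grid points.  Mismatched pairs (gamma off
by >= 20%) fail through the shift of the rise position, which is the
discriminating signal once each curve is normalized by its own plateau.
No continuum SDE integrator is implemented: square-root noise is
numerically fraught, and the discrete simulator *is* the process the
Langevin equations approximate.

## Problem sizes and what the tests show

Monte-Carlo tests use 300–1500 replicates per insertion position,
profiles average 300–500 snapshots, and carrying capacities span
50–3000 (10^4 for speed calibration; 1000 for the substitution-rate
figure), so the whole suite runs on a single CPU in well under half an
hour; all statistical tolerances are expressed in standard errors of the
actual run, so they widen consistently at smaller sample sizes.  The
simulator doubles as the data generator: passing tests show internal
consistency of simulation, theory and asymptotics under the model's
assumptions (haploid, one locus, two alleles, constant per-capita tip
growth, linear habitat).  They do not speak to features real range
expansions have and the model lacks: Allee effects, two-dimensional
fronts with undulations and sectoring, bulk-deleterious mutations,
recombination, clonal interference (mutations are inserted one at a
time, as the rare-mutation regime assumes).

## Known limitations

* The mean-field theory systematically sits slightly below the simulated
  `u(x)` in the rise region at moderate `N` (profile fluctuations help
  rare clones); the agreement criterion absorbs this at the default
  sizes, but the bias grows as `N_tilde` shrinks.
* Near neutrality (`b/a < 1.2`) only the Monte-Carlo route is valid.
* `phi` estimates inherit the window-truncation sensitivity of a product
  of a decaying and a growing exponential; the integral guard refuses
  windows whose edges still carry weight, and with few replicates a
  single lucky deep-bulk fixation can trip that guard — widen the bulk
  side of the grid rather than weakening the guard.
* Asymptotic formulas are leading-order in `ln(N_tilde)` and should not
  be read as quantitative below `N_tilde ~ 100`.
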