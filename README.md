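# genesurf

Gene surfing at one-dimensional range expansions: an individual-based
stepping-stone simulator, the branching-process theory of the surfing
probability, and the substitution rate of recurrent beneficial mutations
at an advancing front.

## The problem

When a population expands into empty territory, the few pioneers at the
wave tip dominate the future gene pool: an allele that happens to ride
the front can "surf" to fixation in the newly colonized range.  For a
beneficial mutation of effect `s = (b - a)/a` (wildtype and mutant
low-density growth rates `a` and `b`), two antagonistic factors set the
rate of such events: the probability `u(x)` that a mutant arising at
front-relative position `x` surfs — which rises steeply toward the tip —
and the mutational input `N c0(x)` — which collapses toward the tip with
the population density `c0`.  `genesurf` measures both in a stochastic
stepping-stone model (demes of carrying capacity `N`, explicit vacancies,
migration and duplication events, noisy FKPP wave with diffusion constant
1 and pulled speed bound `2 sqrt(a)`), predicts `u(x)` from branching
random-walk theory,

    u'' - v u' + b (1 - c0(x)) u - u^2 = 0,
    u(-inf) = 0,  u(+inf) = b,

solved on the measured wave profile `c0` at the measured speed `v`, and
convolves the two factors into the normalized substitution rate

    phi = N * int c0(x) u(x) dx,     Lambda = mu * phi,

with `phi = 1` for neutral mutations (substitution rate = mutation rate).
Closed-form asymptotics (Brunet–Derrida cutoff speeds, deterministic and
finite-N standoff distances, the essential singularity of the
deterministic rate at `s -> 0`) and the two-control-parameter reduction
(`gamma = b/a`, `N_tilde = N sqrt(a)`) round out the analysis chain.  See
`docs/methods.md` for the model, numerics and limitations.

Intended users: population geneticists and statistical physicists
studying evolution at expanding fronts, and anyone needing a calibrated
noisy-FKPP testbed.

## Worked example

Estimate the surfing probability of a mutant inserted 30 demes ahead of
the front (`N = 100`, `a = 0.2`, `b = 0.3`):

```text
$ genesurf surf-prob --N 100 --a 0.2 --b 0.3 --L 120 --x 30 --reps 1000 --seed 11
u(+30.0) = 0.2730 +- 0.0141  (1000 replicates)
```

Far ahead of the front the mutant clone only has to survive its own
demographic fluctuations; the classical establishment probability for a
death/birth ratio `1 - b` is `b = 0.3`, and the measurement agrees within
two standard errors.  The matching closed-form quantities:

```text
$ genesurf asymptotics --a 0.2 --b 0.3 --N 1000 --mode finite
{
  "phi": 122.16519537598703,
  "L_det": 9.46786740762883,
  "L_N": 7.509674524173875,
  "Lc_heuristic": 25.979277234717134
}
```

`L_det` and `L_N` are the deterministic and finite-N standoff distances
(in demes) at which surfing switches on — genetic drift (finite `N`)
pulls the onset toward the front — and `Lc_heuristic` is the
upper-bound-style clone-growth estimate of the same length.  The
asymptotic `phi` is a leading-order estimate and sits well above the
simulated value at this `N_tilde`; the quantitative route is
`genesurf substitution-rate` (see `examples/sweep.csv`), which builds
`phi` from a measured profile and either the theory curve or Monte-Carlo.

Other subcommands: `simulate-wave` (averaged wave profile + speed),
`surf-curve` (full `u(x)` with extracted features `u_inf`, `L_c`,
`Delta`), `theory-bvp` (solve the boundary-value problem on a saved
profile), `collapse-test` (two-parameter data collapse).  Every run
writes CSV results plus a JSON metadata record and is bit-reproducible
from its seed.

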