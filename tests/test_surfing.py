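"""Mutant insertion, outcome classification and curve-feature extraction."""

import numpy as np
import pytest

from genesurf import (ModelParams, BoxState, WaveProfile, classify_outcome,
                      extract_features, insert_mutant)
from genesurf.surfing import (DEATH, FAILURE, FIXATION, SurfingCurve,
                              estimate_surfing_probability, surfing_curve)


def _state(nW, nM, **kw):
    return BoxState(nW=np.asarray(nW, dtype=np.int64),
                    nM=np.asarray(nM, dtype=np.int64), **kw)


class TestInsertMutant:
    def test_converts_wildtype_when_available(self):
        p = ModelParams(N=10, a=0.2, b=0.3, L=10)
        s = _state([10] * 3 + [0] * 7, [0] * 10)
        # front at 2.5; x_offset -1 -> deme 2 (full of wildtype)
        insert_mutant(s, p, -1.0)
        assert s.nW[2] == 9 and s.nM[2] == 1

    def test_converts_vacancy_in_empty_deme(self):
        p = ModelParams(N=10, a=0.2, b=0.3, L=10)
        s = _state([10] * 3 + [0] * 7, [0] * 10)
        insert_mutant(s, p, 4.0)  # front 2.5 -> deme 6, empty
        assert s.nW[6] == 0 and s.nM[6] == 1
        assert (s.nW + s.nM <= 10).all()

    def test_rejects_offset_beyond_box(self):
        p = ModelParams(N=10, a=0.2, b=0.3, L=10)
        s = _state([10] * 3 + [0] * 7, [0] * 10)
        with pytest.raises(ValueError, match="outside box"):
            insert_mutant(s, p, 40.0)


class TestClassifyOutcome:
    def test_fixation_no_wildtype_left(self):
        s = _state([0] * 4, [0, 3, 2, 0])
        assert classify_outcome(s).label == FIXATION

    def test_failure_mutants_crossed_left(self):
        s = _state([5, 5, 0, 0], [0] * 4, mutants_crossed_left=3)
        assert classify_outcome(s).label == FAILURE

    def test_death_mutants_never_crossed(self):
        s = _state([5, 5, 0, 0], [0] * 4, mutants_crossed_left=0)
        assert classify_outcome(s).label == DEATH

    def test_unterminated_run_raises(self):
        s = _state([5, 0], [0, 1])
        with pytest.raises(ValueError, match="not terminated"):
            classify_outcome(s)


def test_zero_replicates_rejected(fast_params):
    with pytest.raises(ValueError):
        estimate_surfing_probability(fast_params, 5.0, n_reps=0)


@pytest.mark.parametrize("grid", [[], [0.0, 2.0, 1.0]])
def test_bad_grids_rejected(fast_params, grid):
    with pytest.raises(ValueError):
        surfing_curve(fast_params, grid, n_reps=10)


def test_extract_features_logistic_closed_form():
    """A synthetic logistic curve has known plateau, onset and 25-75% width."""
    x = np.arange(-10.0, 20.01, 0.25)
    u = 0.3 / (1.0 + np.exp(-(x - 5.0)))
    curve = SurfingCurve(x=x, u=u, se=np.full_like(x, 1e-4),
                         n_reps=np.full(x.size, 10000))
    profile = WaveProfile(x=x, c0=1.0 / (1.0 + np.exp(x)), v=0.9, n_samples=1)
    u_inf, L_c, delta = extract_features(curve, profile)
    assert u_inf == pytest.approx(0.3, abs=1e-3)
    assert L_c == pytest.approx(5.0, abs=0.05)
    assert delta == pytest.approx(2 * np.log(3.0), abs=0.05)


def test_extract_features_requires_plateau():
    x = np.arange(0.0, 10.01, 1.0)
    u = 0.02 * x  # still rising at the right edge
    curve = SurfingCurve(x=x, u=u, se=np.full_like(x, 1e-4),
                         n_reps=np.full(x.size, 10000))
    profile = WaveProfile(x=x - 5, c0=1.0 / (1.0 + np.exp(x - 5)), v=0.9,
                          n_samples=1)
    with pytest.raises(ValueError, match="plateau"):
        extract_features(curve, profile)


def test_outcome_frequencies_partition(relaxed_fast, fast_params):
    """Outcome labels are exhaustive and mutually exclusive over replicates."""
    from genesurf.surfing import surfing_outcomes

    counts = surfing_outcomes(fast_params, 5.0, 200, seed=77,
                              base_state=relaxed_fast)
    labels = ("FIXATION", "FAILURE", "DEATH", "CENSORED")
    assert sum(counts[k] for k in labels) == 200
    assert counts["CENSORED"] == 0
    assert 0.0 <= counts["wu_mean"] <= counts["FIXATION"] / 200 + 1e-12
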