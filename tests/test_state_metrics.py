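import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from statevar.metabolic_model import (
    CONTROL,
    MetaboliteSpec,
    MetabolicModel,
    ReactionSpec,
)
from statevar.ode_engine import Perturbation, Timecourse, simulate
from statevar.state_metrics import (
    EntropyAccumulator,
    StateDistribution,
    StateTrajectory,
    discretize,
    percent_of_max,
    pool_states,
    robustness,
    variation_of_state,
)


def _traj(states, label="run"):
    return StateTrajectory(run_label=label, states=tuple(map(tuple, states)))


def _dist(counts):
    counts = {tuple(k): v for k, v in counts.items()}
    return StateDistribution(counts=counts, total=sum(counts.values()))


class TestDiscretize:
    def _tc(self, values, met="Y"):
        n = len(values)
        return Timecourse(
            times=np.arange(n, dtype=float),
            amounts=np.array(values)[:, None],
            metabolite_ids=(met,),
        )

    def _model(self, baseline=1.0):
        return MetabolicModel(
            metabolites=(
                MetaboliteSpec(
                    id="Y", initial_amount=baseline, is_state_metabolite=True
                ),
            ),
            reactions=(),
            conditions=(CONTROL,),
        )

    def test_above_threshold(self):
        traj = discretize(self._tc([1.0, 2.5]), self._model())
        assert traj.states == ((0,), (1,))

    def test_below_threshold(self):
        traj = discretize(self._tc([1.0, 1.9]), self._model())
        assert traj.states == ((0,), (0,))

    def test_doubled_initial_counts_as_accumulated(self):
        # inclusive threshold: a doubled initial amount registers at t=0
        traj = discretize(self._tc([2.0, 1.0]), self._model())
        assert traj.states[0] == (1,)

    def test_strict_flag(self):
        traj = discretize(self._tc([2.0, 1.0]), self._model(), strict=True)
        assert traj.states[0] == (0,)

    def test_missing_metabolite_errors(self):
        model = self._model()
        tc = self._tc([1.0, 1.0], met="Z")
        with pytest.raises(KeyError, match="Y"):
            discretize(tc, model)

    def test_zero_baseline_errors(self):
        with pytest.raises(ValueError, match="baseline"):
            discretize(self._tc([0.0, 0.0]), self._model(baseline=0.0))

    def test_uses_unperturbed_baseline(self, small_model):
        tc = simulate(small_model, Perturbation(doubled=("Y",)), condition=CONTROL)
        traj = discretize(tc, small_model)
        assert traj.states[0] == (1,)  # doubled initial is exactly 2x baseline


class TestPoolStates:
    def test_sixteen_runs_window(self):
        trajs = [_traj([(0,)] * 5, label=str(k)) for k in range(16)]
        dist = pool_states(trajs, window=(1, 4))
        assert dist.total == 64

    def test_single_run_single_time(self):
        dist = pool_states([_traj([(1, 0)])], window=(0, 0))
        assert dist.total == 1
        assert dist.counts == {(1, 0): 1}

    def test_empty_list_errors(self):
        with pytest.raises(ValueError, match="empty"):
            pool_states([], window=(0, 0))

    def test_window_out_of_range(self):
        with pytest.raises(ValueError, match="window"):
            pool_states([_traj([(0,), (1,)])], window=(1, 2))


class TestVariationOfState:
    def test_uniform_sixteen(self):
        dist = _dist({(i, j, k, l): 1 for i in (0, 1) for j in (0, 1)
                      for k in (0, 1) for l in (0, 1)})
        assert variation_of_state(dist) == pytest.approx(4.0)

    def test_single_state(self):
        assert variation_of_state(_dist({(0, 1): 7})) == 0.0

    def test_half_quarter_quarter(self):
        dist = _dist({(0,): 2, (1,): 1, (2,): 1})
        assert variation_of_state(dist) == pytest.approx(1.5)

    @given(
        counts=st.lists(st.integers(1, 50), min_size=1, max_size=32)
    )
    @settings(max_examples=100, deadline=None)
    def test_bounds_and_permutation_invariance(self, counts):
        states = [(i,) for i in range(len(counts))]
        h = variation_of_state(_dist(dict(zip(states, counts))))
        assert -1e-12 <= h <= math.log2(len(counts)) + 1e-12
        perm = np.random.default_rng(0).permutation(len(counts))
        h2 = variation_of_state(
            _dist({states[i]: counts[perm[i]] for i in range(len(counts))})
        )
        assert h2 == pytest.approx(h, abs=1e-12)

    @given(
        seq=st.lists(st.integers(0, 7), min_size=1, max_size=200)
    )
    @settings(max_examples=100, deadline=None)
    def test_streaming_equals_batch(self, seq):
        acc = EntropyAccumulator()
        for v in seq:
            acc.add((v,))
        batch = variation_of_state(_dist(dict(Counter((v,) for v in seq))))
        assert acc.entropy() == pytest.approx(batch, abs=1e-12)

    def test_streaming_empty_errors(self):
        with pytest.raises(ValueError):
            EntropyAccumulator().entropy()


class TestRobustness:
    def test_all_match(self):
        ref = _traj([(0, 0), (1, 1)])
        runs = [_traj([(1, 1), (0, 0)]) for _ in range(3)]
        assert robustness(runs, ref) == 1.0

    def test_none_match(self):
        ref = _traj([(0, 0)])
        runs = [_traj([(0, 0), (1, 1)])]
        assert robustness(runs, ref) == 0.0

    def test_quarter(self):
        ref = _traj([(0, 0, 0, 0)])
        runs = [_traj([(0, 0, 0, 0), (0, 1, 1, 1)])]
        assert robustness(runs, ref) == 0.25

    def test_mismatched_length_errors(self):
        with pytest.raises(ValueError, match="components"):
            robustness([_traj([(0, 0)])], _traj([(0,)]))

    @given(data=st.data())
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_recount(self, data):
        m = data.draw(st.integers(1, 5))
        n_runs = data.draw(st.integers(1, 6))
        rng_bits = st.lists(
            st.lists(st.integers(0, 1), min_size=m, max_size=m),
            min_size=2, max_size=4,
        )
        ref = _traj(data.draw(rng_bits))
        runs = [_traj(data.draw(rng_bits)) for _ in range(n_runs)]
        expected = np.mean(
            [
                [run.states[-1][j] == ref.states[0][j] for j in range(m)]
                for run in runs
            ]
        )
        assert robustness(runs, ref) == pytest.approx(expected)


class TestPercentOfMax:
    def test_complete_loss_sixteen_states(self):
        assert percent_of_max(0.81, 0.0, 16) == 20

    def test_partial_loss_256_states(self):
        assert percent_of_max(3.80, 2.65, 256) == 14

    def test_no_change(self):
        assert percent_of_max(1.234, 1.234, 64) == 0

    def test_gain_is_negative(self):
        assert percent_of_max(3.80, 4.19, 256) == -5

    def test_small_state_space_errors(self):
        with pytest.raises(ValueError, match="n_states"):
            percent_of_max(1.0, 0.0, 1)


def test_distribution_frame():
    df = _dist({(1, 0): 3, (0, 1): 1}).to_frame()
    assert list(df.columns) == ["state", "count", "probability"]
    assert df["probability"].sum() == pytest.approx(1.0)
    assert set(df["state"]) == {"10", "01"}


def test_distribution_validation():
    with pytest.raises(ValueError, match="total"):
        StateDistribution(counts={(0,): 1}, total=2)
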