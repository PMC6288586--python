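"""Sign-sum gating decision, latency mechanics, simulators, nErr."""

import itertools

import numpy as np
import pytest

import respgate as rg
from respgate.smoothing import SmoothingConfig


class TestSignSum:
    def test_values_at_threshold_count_zero(self):
        assert rg.sign_sum([2.0, 2.0, 2.0], beta=2.0) == 0

    def test_all_below(self):
        assert rg.sign_sum([0.0] * 5, beta=1.0) == -5

    def test_mixed(self):
        assert rg.sign_sum([-1.0, -2.0, 3.0], beta=0.0) == -1

    def test_bounds(self, rng):
        a = rng.normal(size=9)
        assert -9 <= rg.sign_sum(a, 0.0) <= 9

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rg.sign_sum([], 0.0)


class TestGateDecision:
    def test_both_windows_below_gives_on_in_both_orderings(self):
        on = [0.0] * 5   # 2*m1+1 with m1=2
        off = [0.0] * 3  # 2*m0+1 with m0=1
        assert rg.gate_decision(on, off, beta=1.0, m1=2, m0=1) == 1
        assert rg.gate_decision(off, on, beta=1.0, m1=1, m0=2) == 1

    def test_both_windows_above_gives_off(self):
        on, off = [5.0] * 5, [5.0] * 3
        assert rg.gate_decision(on, off, beta=1.0, m1=2, m0=1) == 0
        assert rg.gate_decision(off, on, beta=1.0, m1=1, m0=2) == 0

    def test_or_versus_and_asymmetry(self):
        below, above = [0.0] * 5, [5.0] * 3
        # m1 >= m0: one window below suffices (OR)
        assert rg.gate_decision(below, above, beta=1.0, m1=2, m0=1) == 1
        # m1 < m0: both must be below (AND); same tuples, swapped roles
        assert rg.gate_decision(above, below, beta=1.0, m1=1, m0=2) == 0

    def test_exactly_at_threshold_is_off(self):
        on, off = [1.0] * 5, [1.0] * 3
        assert rg.gate_decision(on, off, beta=1.0, m1=2, m0=1) == 0
        assert rg.gate_decision(off, on, beta=1.0, m1=1, m0=2) == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rg.gate_decision([0.0] * 4, [0.0] * 3, beta=1.0, m1=2, m0=1)
        with pytest.raises(ValueError):
            rg.gate_decision([0.0] * 5, [0.0] * 2, beta=1.0, m1=2, m0=1)

    def test_equal_latencies_make_orderings_agree_when_signs_agree(self):
        """With m1 == m0 the OR and AND forms coincide whenever the two
        window conditions agree; enumerate all sign patterns of 3-point
        windows."""
        vals = [-1.0, 0.0, 1.0]
        for w_on in itertools.product(vals, repeat=3):
            for w_off in itertools.product(vals, repeat=3):
                c_on = rg.sign_sum(w_on, 0.0) < 0
                c_off = rg.sign_sum(w_off, 0.0) < 0
                d = rg.gate_decision(w_on, w_off, beta=0.0, m1=1, m0=1)
                if c_on == c_off:
                    assert d == int(c_on)  # OR == AND here


class TestApplyLatency:
    def test_zero_latency_is_identity(self, rng):
        d = (rng.random(50) < 0.5).astype(int)
        assert np.array_equal(rg.apply_latency(d, 0, 0), d)

    def test_hand_stepped_example(self):
        realized = rg.apply_latency([0, 0, 1, 1, 1, 0, 0, 0], m1=2, m0=1)
        assert np.array_equal(realized, [0, 0, 0, 0, 1, 1, 0, 0])

    def test_constant_desired(self):
        assert np.array_equal(rg.apply_latency([0] * 6, 2, 1), [0] * 6)
        assert np.array_equal(rg.apply_latency([1] * 6, 2, 1),
                              [0, 0, 1, 1, 1, 1])
        assert np.array_equal(
            rg.apply_latency([1] * 6, 2, 1, initial_state=1), [1] * 6
        )

    def test_command_overtaking_uses_later_issue_on_ties(self):
        # on at t=0 executes t=3; off at t=1 executes t=3 too: off wins
        realized = rg.apply_latency([1, 0, 0, 0, 0], m1=3, m0=2)
        assert np.array_equal(realized, [0, 0, 0, 0, 0])

    def test_deviations_confined_near_transitions(self, rng):
        m1, m0 = 4, 2
        # well-separated transitions: > m1 + m0 apart
        d = np.zeros(200, dtype=int)
        for start in (20, 60, 120):
            d[start : start + 25] = 1
        realized = rg.apply_latency(d, m1, m0)
        diff = np.flatnonzero(realized != d)
        edges = np.flatnonzero(np.diff(d)) + 1
        assert all(min(abs(j - e) for e in edges) < max(m1, m0) for j in diff)


def _small_config(m1, m0, **kw):
    return rg.GatingConfig(m1=m1, m0=m0, N=60, n=8, **kw)


class TestSimulateConventional:
    def test_zero_latency_matches_ideal_thresholding(self, rng):
        sig = rg.RespiratorySignal(rng.normal(size=120), 0.03)
        cfg = _small_config(0, 0, beta=0.0)
        trace = rg.simulate_conventional(sig, cfg)
        assert np.array_equal(trace.states, (sig.values < 0.0).astype(int))
        assert rg.nerr(sig, trace, 0.0) == 0.0

    def test_signal_entirely_above_threshold_keeps_beam_off(self):
        sig = rg.RespiratorySignal(np.full(100, 5.0), 0.03)
        cfg = _small_config(3, 1, beta=0.0)
        trace = rg.simulate_conventional(sig, cfg)
        assert not trace.states.any()

    def test_windows_shift_by_latency_on_square_wave(self):
        # one threshold crossing per half-cycle, crossings far apart
        cycle = [5.0] * 20 + [-5.0] * 20
        sig = rg.RespiratorySignal(np.array(cycle * 5), 0.03)
        m1, m0 = 2, 1
        cfg = _small_config(m1, m0, beta=0.0)
        trace = rg.simulate_conventional(sig, cfg)
        ideal = (sig.values < 0.0).astype(int)
        expected = rg.apply_latency(ideal, m1, m0)
        assert np.array_equal(trace.states, expected)
        on_edges = np.flatnonzero(np.diff(trace.states) == 1) + 1
        ideal_on = np.flatnonzero(np.diff(ideal) == 1) + 1
        assert all((e - i) == m1 for e, i in
                   zip(on_edges, ideal_on[: len(on_edges)]))

    def test_short_signal_rejected(self):
        sig = rg.RespiratorySignal(np.ones(30), 0.03)
        with pytest.raises(ValueError):
            rg.simulate_conventional(sig, _small_config(2, 1, beta=0.0))


class TestSimulatePredictive:
    def test_constant_signal_below_threshold_turns_beam_on(self):
        sig = rg.RespiratorySignal(np.full(120, -1.0), 0.03)
        cfg = _small_config(2, 1, beta=0.0)
        trace = rg.simulate_predictive(sig, cfg)
        # warm-up off, then permanently on once commands execute
        assert trace.states[-20:].all()
        assert not trace.states[: cfg.N + cfg.n].any()

    def test_zero_latency_reduces_to_one_point_prediction(self, rng):
        x = rng.normal(size=150)
        sig = rg.RespiratorySignal(x, 0.03)
        cfg = _small_config(0, 0, beta=0.0)
        trace = rg.simulate_predictive(sig, cfg)
        # reproduce the decision path with the public building blocks
        N, n = cfg.N, cfg.n
        for t in range(N + n, len(sig)):
            ls = rg.build_learning_set(x[t - n - N : t - n], n, 1)
            pred = rg.nn_predict(ls, x[t - n : t])
            assert trace.states[t] == int(pred[0] < 0.0)

    def test_matches_composition_of_public_operations(self):
        """Dual-route check: the simulator must equal learning-set
        construction + NN lookup + gate decision + latency application."""
        sig = rg.generate(
            rg.preset("volunteer_regular", seed=5, duration=9.0, dt=0.06)
        )
        cfg = rg.GatingConfig(m1=3, m0=2, N=60, n=10, beta=2.0,
                              smoothing=SmoothingConfig(alpha=5.0))
        trace = rg.simulate_predictive(sig, cfg)
        x = sig.values
        desired = np.zeros(len(sig), dtype=int)
        for t in range(cfg.N + cfg.n, len(sig)):
            window = x[t - cfg.n - cfg.N : t - cfg.n]
            ls1 = rg.build_learning_set(window, cfg.n, 2 * cfg.m1 + 1,
                                        cfg.smoothing, dt=sig.dt)
            ls0 = rg.build_learning_set(window, cfg.n, 2 * cfg.m0 + 1,
                                        cfg.smoothing, dt=sig.dt)
            q = x[t - cfg.n : t]
            desired[t] = rg.gate_decision(
                rg.nn_predict(ls1, q), rg.nn_predict(ls0, q),
                cfg.beta, cfg.m1, cfg.m0,
            )
        expected = rg.apply_latency(desired, cfg.m1, cfg.m0)
        assert np.array_equal(trace.states, expected)

    def test_oracle_predictor_compensates_clean_square_wave(self):
        """With perfect forecasts the decision windows centred on the
        execution times realign the gating windows; the predictive route
        must score strictly below the conventional one."""
        cycle = [5.0] * 20 + [-5.0] * 20
        x = np.array(cycle * 6, dtype=float)
        sig = rg.RespiratorySignal(x, 0.03)
        m1, m0, N, n = 2, 1, 60, 8
        beta = 0.0
        desired = np.zeros(x.size, dtype=int)
        for t in range(N + n, x.size):
            # substitute the true future for the forecasts
            w_on = x[t : t + 2 * m1 + 1]
            w_off = x[t : t + 2 * m0 + 1]
            if w_on.size < 2 * m1 + 1 or w_off.size < 2 * m0 + 1:
                desired[t] = desired[t - 1]
                continue
            desired[t] = rg.gate_decision(w_on, w_off, beta, m1, m0)
        realized = rg.apply_latency(desired, m1, m0)
        oracle_trace = rg.GateTrace(states=realized, scored_start=N + n + m1 - 1)
        cfg = rg.GatingConfig(m1=m1, m0=m0, N=N, n=n, beta=beta)
        conv = rg.simulate_conventional(sig, cfg)
        assert rg.nerr(sig, oracle_trace, beta) < rg.nerr(sig, conv, beta)
        # windows align with the ideal ones up to one point near crossings
        # (after the first issued command has had time to execute)
        ideal = (x < beta).astype(int)
        S = oracle_trace.scored_set
        diff = np.flatnonzero(realized[S] != ideal[S]) + S[0]
        diff = diff[diff >= N + n + m1]
        edges = np.flatnonzero(np.diff(ideal)) + 1
        assert all(min(abs(j - e) for e in edges) <= 1 for j in diff)


def test_baseline_drift_erodes_the_predictive_advantage():
    """Fixed-threshold gating degrades under baseline drift; the relative
    benefit of prediction (nErr ratio predictive/conventional) must shrink
    markedly compared to drift-free breathing.  Weak assertion: the
    predictive arm may even lose on drifting signals."""
    smoothing = SmoothingConfig(cutoff_hz=1.0)
    ratios = {}
    for name in ("volunteer_regular", "volunteer_drift"):
        sig = rg.generate(rg.preset(name, seed=1))
        cfg = rg.GatingConfig(m1=12, m0=3, N=1500, n=60, smoothing=smoothing)
        beta = cfg.resolve_beta(sig)
        nc = rg.nerr(sig, rg.simulate_conventional(sig, cfg), beta)
        npred = rg.nerr(sig, rg.simulate_predictive(sig, cfg), beta)
        ratios[name] = npred / nc
    assert ratios["volunteer_drift"] > 10 * ratios["volunteer_regular"]


class TestNerr:
    def test_hand_computed_example(self):
        sig = rg.RespiratorySignal(np.array([1.0, -1.0, 2.0, -2.0]), 0.03)
        trace = rg.GateTrace(states=np.array([1, 1, 0, 0]), scored_start=0)
        assert rg.nerr(sig, trace, beta=0.0) == pytest.approx(0.75)

    def test_ideal_gating_scores_zero(self, rng):
        x = rng.normal(size=50)
        sig = rg.RespiratorySignal(x, 0.03)
        trace = rg.GateTrace(states=(x < 0.2).astype(int), scored_start=0)
        assert rg.nerr(sig, trace, beta=0.2) == 0.0

    def test_beam_always_on_below_threshold_scores_zero(self):
        sig = rg.RespiratorySignal(np.full(20, -3.0), 0.03)
        trace = rg.GateTrace(states=np.ones(20, dtype=int), scored_start=5)
        assert rg.nerr(sig, trace, beta=0.0) == 0.0

    def test_nonnegative_and_shift_invariant(self, rng):
        x = rng.normal(size=80)
        sig = rg.RespiratorySignal(x, 0.03)
        states = (rng.random(80) < 0.5).astype(int)
        trace = rg.GateTrace(states=states, scored_start=10)
        base = rg.nerr(sig, trace, beta=0.3)
        assert base >= 0.0
        shifted = rg.RespiratorySignal(x + 5.0, 0.03)
        assert rg.nerr(shifted, trace, beta=5.3) == pytest.approx(base)


class TestGateTrace:
    def test_scored_partition(self):
        trace = rg.GateTrace(states=np.array([0, 1, 1, 0, 1]), scored_start=1)
        assert np.array_equal(trace.scored_set, [1, 2, 3, 4])
        assert np.array_equal(trace.on_set, [1, 2, 4])
        assert np.array_equal(trace.off_set, [3])
        assert set(trace.on_set) | set(trace.off_set) == set(trace.scored_set)

    def test_scored_set_size_matches_formula(self, regular_signal):
        cfg = rg.GatingConfig(m1=12, m0=3, N=1500, n=60)
        trace = rg.simulate_conventional(regular_signal, cfg)
        M = len(regular_signal)
        assert trace.scored_set.size == M - cfg.N - cfg.n - cfg.m1 + 1

    def test_invalid_traces_rejected(self):
        with pytest.raises(ValueError):
            rg.GateTrace(states=np.array([0, 2]), scored_start=0)
        with pytest.raises(ValueError):
            rg.GateTrace(states=np.array([0, 1]), scored_start=5)


class TestGatingConfig:
    def test_window_must_fit_history_and_lookahead(self):
        with pytest.raises(ValueError):
            rg.GatingConfig(m1=10, m0=3, N=25, n=8)
        rg.GatingConfig(m1=10, m0=3, N=29, n=8)  # n + 2*m1+1 = 29 fits

    def test_negative_latency_rejected(self):
        with pytest.raises(ValueError):
            rg.GatingConfig(m1=-1, m0=0, N=60, n=8)

    def test_beta_defaults_to_initial_median(self, regular_signal):
        cfg = rg.GatingConfig(m1=12, m0=3, N=1500, n=60)
        assert cfg.resolve_beta(regular_signal) == rg.gating_threshold(
            regular_signal, 1500
        )
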