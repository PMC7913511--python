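"""Viterbi and forward-backward decoding against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, seed, settings, strategies as st

import calvehmm as ch

from conftest import random_hmm
from oracles import enumerate_best_path, pathsum_posteriors


def _uniform_params():
    return ch.HMMParams(A=np.full((2, 2), 0.5), B=np.full((2, 3), 1 / 3),
                        Pi=np.array([0.5, 0.5]))


class TestViterbi:
    def test_single_high_observation_decodes_calving(self, fitted_params):
        # P(C)b_C(H) = 0.5*0.308 beats P(NC)b_NC(H) = 0.5*0.135.
        path, ll = ch.viterbi(fitted_params, ["H"])
        assert path == ("C",)
        assert ll == pytest.approx(np.log(0.5 * fitted_params.B[1, 2]))

    def test_reference_record_decodes_all_non_calving(self, fitted_params, cow1_windowed):
        # Entering C costs a12*b_C(H) = 0.016*0.308, staying NC 0.984*0.135:
        # under this model the joint-mode path never leaves NC, even though
        # the final 3-h interval is high activity.
        path, _ = ch.viterbi(fitted_params, cow1_windowed)
        assert path == ("NC",) * 24

    def test_uniform_model_ties_break_toward_non_calving(self):
        path, _ = ch.viterbi(_uniform_params(), ["L", "M", "H"])
        assert path == ("NC",) * 3

    def test_unknown_symbol_rejected(self, fitted_params):
        with pytest.raises(ValueError, match="alphabet"):
            ch.viterbi(fitted_params, ["L", "X"])

    def test_impossible_observation_gives_minus_inf(self):
        # b(NC, H) = b(C, H) = 0: no feasible path, sentinel log-likelihood.
        params = ch.HMMParams(A=np.full((2, 2), 0.5),
                              B=np.array([[0.5, 0.5, 0.0], [0.5, 0.5, 0.0]]),
                              Pi=np.array([0.5, 0.5]))
        path, ll = ch.viterbi(params, ["H"])
        assert len(path) == 1 and ll == -np.inf

    @given(data=st.data())
    @seed(20240601)
    @settings(max_examples=60, deadline=None)
    def test_matches_exhaustive_enumeration(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        T = data.draw(st.integers(1, 12))
        params = random_hmm(rng)
        obs_idx = rng.integers(0, 3, size=T)
        obs = ["LMH"[i] for i in obs_idx]
        path, ll = ch.viterbi(params, obs)
        _, best_ll = enumerate_best_path(params.A, params.B, params.Pi, obs_idx)
        assert ll == pytest.approx(best_ll, abs=1e-10)


class TestForwardBackward:
    def test_single_observation_posterior(self, fitted_params):
        # gamma(C) = 0.5*0.308 / (0.5*0.308 + 0.5*0.135) ~= 0.695
        gamma = ch.forward_backward(fitted_params, ["H"])
        b = fitted_params.B
        assert gamma[0] == pytest.approx(b[1, 2] / (b[1, 2] + b[0, 2]), abs=1e-12)

    @given(data=st.data())
    @seed(20240602)
    @settings(max_examples=40, deadline=None)
    def test_matches_path_sum_marginals(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        T = data.draw(st.integers(1, 10))
        params = random_hmm(rng)
        obs_idx = rng.integers(0, 3, size=T)
        gamma = ch.forward_backward(params, ["LMH"[i] for i in obs_idx])
        exact = pathsum_posteriors(params.A, params.B, params.Pi, obs_idx)
        assert np.max(np.abs(gamma - exact[:, 1])) < 1e-10

    def test_long_sequence_is_numerically_stable(self, fitted_params):
        rng = np.random.default_rng(5)
        _, symbols = ch.simulate_symbols(fitted_params, 10_000, rng)
        gamma = ch.forward_backward(fitted_params, symbols)
        ll = ch.sequence_log_likelihood(fitted_params, symbols)
        assert np.isfinite(ll)
        assert np.all((gamma >= 0) & (gamma <= 1))
        path, vit_ll = ch.viterbi(fitted_params, symbols)
        assert np.isfinite(vit_ll) and len(path) == 10_000

    def test_appending_high_evidence_never_lowers_final_posterior(self, fitted_params):
        obs = list("LLLLMLLL")
        prev = ch.forward_backward(fitted_params, obs)[-1]
        for _ in range(6):
            obs.append("H")
            cur = ch.forward_backward(fitted_params, obs)[-1]
            assert cur >= prev - 1e-12
            prev = cur


class TestAgainstHmmlearn:
    """Cross-check decoding against an independent HMM implementation."""

    def _to_hmmlearn(self, params):
        from hmmlearn.hmm import CategoricalHMM

        m = CategoricalHMM(n_components=2)
        m.startprob_ = params.Pi
        m.transmat_ = params.A
        m.emissionprob_ = params.B
        return m

    def test_viterbi_and_likelihood_agree(self, fitted_params, cow1_windowed):
        m = self._to_hmmlearn(fitted_params)
        obs_idx = np.array([["L", "M", "H"].index(s) for s in cow1_windowed.symbols])
        ref_ll, ref_path = m.decode(obs_idx.reshape(-1, 1), algorithm="viterbi")
        path, ll = ch.viterbi(fitted_params, cow1_windowed)
        assert [("NC", "C")[i] for i in ref_path] == list(path)
        assert ll == pytest.approx(ref_ll, abs=1e-9)

    def test_posteriors_agree(self, fitted_params, cow1_windowed):
        m = self._to_hmmlearn(fitted_params)
        obs_idx = np.array([["L", "M", "H"].index(s) for s in cow1_windowed.symbols])
        ref = m.predict_proba(obs_idx.reshape(-1, 1))
        gamma = ch.forward_backward(fitted_params, cow1_windowed)
        assert np.max(np.abs(gamma - ref[:, 1])) < 1e-9


class TestPredictCalvingTime:
    def test_max_posterior_selects_final_interval(self, fitted_params, cow1_windowed):
        res = ch.predict_calving_time(fitted_params, cow1_windowed, "max_posterior")
        assert res.predicted_interval == 23  # 0-based: the last 3-h window
        assert res.strategy == "max_posterior"

    def test_viterbi_onset_makes_no_call_on_reference_record(self, fitted_params, cow1_windowed):
        res = ch.predict_calving_time(fitted_params, cow1_windowed, "viterbi_onset")
        assert res.predicted_interval is None

    def test_viterbi_onset_finds_separable_run(self, fitted_params):
        # Strong emissions + long terminal H run: the joint mode enters C.
        params = ch.HMMParams(A=fitted_params.A,
                              B=np.array([[0.8, 0.15, 0.05], [0.05, 0.15, 0.8]]),
                              Pi=np.array([0.5, 0.5]))
        obs = ["L"] * 10 + ["H"] * 8
        res = ch.predict_calving_time(params, obs, "viterbi_onset")
        assert res.predicted_interval == 10

    def test_posterior_threshold_first_crossing(self, fitted_params, cow1_windowed):
        res = ch.predict_calving_time(fitted_params, cow1_windowed,
                                      "posterior_threshold", threshold=0.1)
        gamma = res.posteriors
        assert res.predicted_interval == int(np.flatnonzero(gamma >= 0.1)[0])
        none = ch.predict_calving_time(fitted_params, cow1_windowed,
                                       "posterior_threshold", threshold=0.999)
        assert none.predicted_interval is None

    def test_invalid_strategy_and_threshold(self, fitted_params, cow1_windowed):
        with pytest.raises(ValueError, match="unknown strategy"):
            ch.predict_calving_time(fitted_params, cow1_windowed, "magic")
        with pytest.raises(ValueError, match="threshold"):
            ch.predict_calving_time(fitted_params, cow1_windowed,
                                    "posterior_threshold", threshold=1.5)

    def test_result_invariants(self, fitted_params, cow1_windowed):
        res = ch.predict_calving_time(fitted_params, cow1_windowed)
        assert len(res.path) == len(res.posteriors) == 24
        assert np.all((res.posteriors >= 0) & (res.posteriors <= 1))
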