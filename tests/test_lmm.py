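"""Likelihood, forward-backward and EM behaviour of the latent Markov model."""

from __future__ import annotations

import math

import numpy as np
import pytest

from conftest import brute_force_inference, random_params, random_subject
from shiftmarkov.lmm import (
    EMConfig,
    LMMParams,
    NumericalError,
    count_params,
    em_fit,
    forward_backward,
    loglik_dataset,
    order_states,
    window_log_emission,
)
from shiftmarkov.preprocess import WindowedCounts
from shiftmarkov.simulate import GeneratorConfig, default_truth, generate


class TestWindowLogEmission:
    @pytest.mark.parametrize(
        "counts, phi_s, expected",
        [
            ((5, 0, 0), (1.0, 0.0, 0.0), 0.0),
            ((1, 1, 0), (0.5, 0.5, 0.0), 2 * math.log(0.5)),
            ((2, 1, 1), (0.93, 0.02, 0.05), math.log(0.93**2 * 0.02 * 0.05)),
        ],
    )
    def test_closed_forms(self, counts, phi_s, expected):
        got = window_log_emission(np.array(counts), np.array(phi_s))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_probability_with_positive_count(self):
        assert window_log_emission(np.array([0, 1, 0]), np.array([1.0, 0.0, 0.0])) == -math.inf

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            window_log_emission(np.array([1, 2]), np.array([0.5, 0.3, 0.2]))


class TestForwardBackward:
    def test_matches_enumeration(self, rng):
        """loglik, gamma and xi agree with exhaustive path enumeration."""
        for _ in range(20):
            S = int(rng.integers(1, 4))
            params = random_params(rng, S)
            subject = random_subject(rng, T=5, group=int(rng.integers(2)))
            ll, gamma, xi = forward_backward(subject, params)
            ll_ref, gamma_ref, xi_ref = brute_force_inference(
                subject.counts, subject.group, params
            )
            assert ll == pytest.approx(ll_ref, abs=1e-10)
            np.testing.assert_allclose(gamma, gamma_ref, atol=1e-10)
            np.testing.assert_allclose(xi, xi_ref, atol=1e-10)

    def test_single_state_degenerates_to_emission_sum(self, rng):
        params = random_params(rng, S=1)
        subject = random_subject(rng, group=1)
        ll, gamma, _ = forward_backward(subject, params)
        expected = sum(
            window_log_emission(row, params.phi[0]) for row in subject.counts
        )
        assert ll == pytest.approx(expected, abs=1e-12)
        assert np.all(gamma == 1.0)

    def test_identity_transitions_mix_over_states(self, rng):
        """With P = I and uniform start only S constant paths survive."""
        S = 3
        params = LMMParams(
            phi=rng.dirichlet(np.ones(3), size=S),
            pi_init=np.full((1, S), 1.0 / S),
            trans=np.eye(S)[None],
        )
        subject = random_subject(rng, group=0)
        ll, _, _ = forward_backward(subject, params)
        per_state = [
            sum(window_log_emission(row, params.phi[s]) for row in subject.counts)
            for s in range(S)
        ]
        m = max(per_state)
        expected = math.log(sum(math.exp(v - m) for v in per_state) / S) + m
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_no_underflow_with_huge_windows(self, rng):
        """Scaling keeps thousands of trials per window finite."""
        params = random_params(rng, S=3)
        counts = rng.multinomial(2000, [0.6, 0.3, 0.1], size=5)
        subject = WindowedCounts("big", 0, counts.sum(axis=1).tolist(), counts)
        ll, gamma, _ = forward_backward(subject, params)
        assert np.isfinite(ll)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-12)

    def test_impossible_data_raises(self):
        params = LMMParams(
            phi=np.array([[1.0, 0.0, 0.0]]),
            pi_init=np.array([[1.0]]),
            trans=np.array([[[1.0]]]),
        )
        subject = WindowedCounts("s", 0, [2], np.array([[0, 1, 1]]))
        with pytest.raises(NumericalError):
            forward_backward(subject, params)

    def test_group_out_of_range(self, rng):
        params = random_params(rng, S=2, G=1)
        subject = random_subject(rng, group=1)
        with pytest.raises(ValueError):
            forward_backward(subject, params)


class TestLoglikDataset:
    def test_additivity_and_oracle(self, rng):
        params = random_params(rng, S=2)
        subject = random_subject(rng, group=1)
        single, _, _ = forward_backward(subject, params)
        assert loglik_dataset([subject], params) == pytest.approx(single, abs=1e-12)
        assert loglik_dataset([subject, subject], params) == pytest.approx(
            2 * single, abs=1e-10
        )
        ll_ref, _, _ = brute_force_inference(subject.counts, subject.group, params)
        assert single == pytest.approx(ll_ref, abs=1e-10)


class TestOrderStates:
    def test_already_ordered_is_identity(self, truth):
        ordered = order_states(truth)
        np.testing.assert_array_equal(ordered.phi, truth.phi)
        np.testing.assert_array_equal(ordered.trans, truth.trans)

    def test_sorts_by_correct_probability(self, truth):
        perm = [1, 2, 0]  # phi C-column becomes (0.80, 0.44, 0.93)
        scrambled = truth.permuted(perm)
        restored = order_states(scrambled)
        np.testing.assert_allclose(restored.phi, truth.phi)
        np.testing.assert_allclose(restored.pi_init, truth.pi_init)
        np.testing.assert_allclose(restored.trans, truth.trans)

    def test_tie_broken_by_perseverative_column(self):
        phi = np.array([[0.5, 0.1, 0.4], [0.5, 0.3, 0.2]])
        params = LMMParams(
            phi=phi,
            pi_init=np.array([[0.3, 0.7]]),
            trans=np.array([[[0.5, 0.5], [0.2, 0.8]]]),
        )
        ordered = order_states(params)
        # equal P(C|s): the state with smaller P(PE|s) comes first
        np.testing.assert_array_equal(ordered.phi, phi[[1, 0]])

    def test_posteriors_permuted_consistently(self, truth, rng):
        post = rng.dirichlet(np.ones(3), size=(4, 5))
        scrambled = truth.permuted([2, 0, 1])
        scrambled_post = post[..., [2, 0, 1]]
        _, restored_post = order_states(scrambled, scrambled_post)
        np.testing.assert_allclose(restored_post, post)


class TestEMFit:
    def test_single_state_closed_form(self, small_cohort):
        """S=1 emission estimate is the pooled empirical category frequency."""
        fit = em_fit(small_cohort.windowed, 1, EMConfig(seed=0, n_starts=1))
        totals = np.sum([w.counts for w in small_cohort.windowed], axis=(0, 1))
        np.testing.assert_allclose(fit.params.phi[0], totals / totals.sum(), atol=1e-9)
        assert fit.converged

    def test_trace_monotone_and_posteriors_normalised(self, small_cohort):
        fit = em_fit(small_cohort.windowed, 2, EMConfig(seed=7, n_starts=3))
        for trace in fit.restart_traces:
            diffs = np.diff(trace)
            assert (diffs >= -1e-8).all()
        np.testing.assert_allclose(fit.posteriors.sum(axis=2), 1.0, atol=1e-10)

    def test_two_state_recovery(self):
        """Well-separated 2-state truth is recovered within binomial error."""
        truth = LMMParams(
            phi=np.array([[0.9, 0.05, 0.05], [0.2, 0.4, 0.4]]),
            pi_init=np.array([[0.6, 0.4], [0.3, 0.7]]),
            trans=np.array(
                [[[0.8, 0.2], [0.3, 0.7]], [[0.6, 0.4], [0.1, 0.9]]]
            ),
        )
        data = generate(
            GeneratorConfig(
                n_control=250, n_sdi=250, trials_per_subject=125, truth=truth, seed=99
            )
        )
        fit = em_fit(data.windowed, 2, EMConfig(seed=5, n_starts=8))
        assert np.abs(fit.params.phi - truth.phi).max() < 0.03
        assert np.abs(fit.params.pi_init - truth.pi_init).max() < 0.06

    def test_relabelled_truth_gives_same_canonical_fit(self):
        """Label switching in the generative truth is invisible after ordering."""
        truth = default_truth()
        cfg = dict(n_control=80, n_sdi=80, trials_per_subject=125, seed=41)
        data_a = generate(GeneratorConfig(truth=truth, **cfg))
        data_b = generate(GeneratorConfig(truth=truth.permuted([2, 0, 1]), **cfg))
        em = EMConfig(seed=3, n_starts=6)
        fit_a = em_fit(data_a.windowed, 3, em)
        fit_b = em_fit(data_b.windowed, 3, em)
        # same canonical parameterisation up to estimation noise between
        # the two (differently permuted, hence differently sampled) cohorts
        assert np.abs(fit_a.params.phi - fit_b.params.phi).max() < 0.08

    def test_seed_determinism(self, small_cohort):
        a = em_fit(small_cohort.windowed, 2, EMConfig(seed=11, n_starts=3))
        b = em_fit(small_cohort.windowed, 2, EMConfig(seed=11, n_starts=3))
        assert a.loglik == b.loglik
        np.testing.assert_array_equal(a.params.phi, b.params.phi)

    def test_pooled_fit_ignores_groups(self, small_cohort):
        fit = em_fit(small_cohort.windowed, 2, EMConfig(seed=2, n_starts=3), n_groups=1)
        assert fit.params.G == 1

    def test_empty_group_rejected(self, small_cohort):
        controls = [w for w in small_cohort.windowed if w.group == 0]
        with pytest.raises(ValueError):
            em_fit(controls, 2, EMConfig(seed=0, n_starts=1), n_groups=2)

    def test_overfitted_state_flags_degenerate(self):
        """Asking for more states than the data identify sets the warning flag."""
        truth = LMMParams(
            phi=np.array([[1.0, 0.0, 0.0]]),
            pi_init=np.array([[1.0], [1.0]]),
            trans=np.array([[[1.0]], [[1.0]]]),
        )
        data = generate(
            GeneratorConfig(n_control=20, n_sdi=20, trials_per_subject=50, truth=truth, seed=1)
        )
        fit = em_fit(data.windowed, 2, EMConfig(seed=4, n_starts=4))
        assert fit.degenerate

    def test_information_criteria_identities(self, small_cohort):
        fit = em_fit(small_cohort.windowed, 2, EMConfig(seed=9, n_starts=2))
        k = count_params(2, 3, 2, 5, True)
        assert fit.n_params == k
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * k)
        assert fit.bic == pytest.approx(-2 * fit.loglik + k * math.log(fit.n_subjects))


class TestSerialization:
    def test_json_round_trip(self, truth, tmp_path):
        path = tmp_path / "params.json"
        truth.to_json(path)
        back = LMMParams.from_json(path)
        np.testing.assert_array_equal(back.phi, truth.phi)
        np.testing.assert_array_equal(back.pi_init, truth.pi_init)
        np.testing.assert_array_equal(back.trans, truth.trans)
        assert back.homogeneous == truth.homogeneous

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError):
            LMMParams(
                phi=np.array([[0.5, 0.5, 0.5]]),
                pi_init=np.array([[1.0]]),
                trans=np.array([[[1.0]]]),
            )
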