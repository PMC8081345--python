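"""Phase-pattern statistics, reconstruction, connectivity, dwell times, D."""

import numpy as np
import pytest

from metapac import (
    MultichannelSeries,
    PPCModel,
    StateLabeling,
    dwell_statistics,
    estimate_fluctuation_level,
    extract_phases,
    fluctuation_covariance,
    ppc_from_patterns,
    reconstruct_patterns,
    state_phase_stats,
    wrap_phase,
)
from metapac.estimation import PhasePatternSet
from metapac.pipeline import circular_similarity


class TestExtractPhases:
    def test_cosine_phase_advances_at_carrier_rate(self):
        fs, f1 = 100.0, 1.0
        t = np.arange(60 * 100) / fs
        x = MultichannelSeries(np.cos(2 * np.pi * f1 * t)[None, :], fs)
        theta = extract_phases(x, f1)
        slope = np.polyfit(theta.times, np.unwrap(theta.data[0]), 1)[0]
        assert slope == pytest.approx(2 * np.pi * f1, rel=0.01)
        assert np.all(theta.data > -np.pi) and np.all(theta.data <= np.pi)

    def test_two_channels_with_known_offset(self):
        fs, f1, off = 100.0, 1.0, np.pi / 3
        t = np.arange(60 * 100) / fs
        data = np.vstack([np.cos(2 * np.pi * f1 * t),
                          np.cos(2 * np.pi * f1 * t + off)])
        theta = extract_phases(MultichannelSeries(data, fs), f1)
        diff = wrap_phase(theta.data[1] - theta.data[0])
        assert np.abs(np.median(diff) - off) < 0.02


class TestStatePhaseStats:
    def test_locked_channels_give_unit_index_and_known_difference(self, rng):
        t = np.linspace(0, 20, 800)
        base = 2 * np.pi * t
        delta = 0.7
        theta = np.vstack([base, base + delta])
        labels = StateLabeling(np.ones(800, dtype=int), K=1)
        stats = state_phase_stats(wrap_phase(theta), labels)
        assert stats.R[0, 0, 1] == pytest.approx(1.0)
        assert stats.psi[0, 1, 0] == pytest.approx(delta, abs=1e-9)
        assert stats.psi[0, 0, 1] == pytest.approx(-delta, abs=1e-9)
        np.testing.assert_allclose(np.diagonal(stats.R[0]), 1.0)
        np.testing.assert_allclose(np.diagonal(stats.psi[0]), 0.0, atol=1e-12)

    def test_independent_phases_have_low_index(self, rng):
        theta = rng.uniform(-np.pi, np.pi, size=(2, 500))
        labels = StateLabeling(np.ones(500, dtype=int), K=1)
        stats = state_phase_stats(theta, labels)
        assert stats.R[0, 0, 1] < 0.2  # Rayleigh scale ~ 1/sqrt(n)

    def test_unvisited_state_rejected(self, rng):
        theta = rng.uniform(-np.pi, np.pi, size=(2, 50))
        labels = StateLabeling(np.ones(50, dtype=int), K=2)
        with pytest.raises(ValueError, match="never visited"):
            state_phase_stats(theta, labels)


class TestReconstructPatterns:
    def test_noiseless_offsets_recovered_up_to_rotation(self):
        true = np.array([0.0, 1.0, -2.0, 0.5])
        t = np.linspace(0, 30, 2000)
        theta = wrap_phase(2 * np.pi * t[None, :] + true[:, None])
        labels = StateLabeling(np.ones(2000, dtype=int), K=1)
        stats = reconstruct_patterns(state_phase_stats(theta, labels))
        assert circular_similarity(true, stats.patterns[0]) == pytest.approx(1.0, abs=1e-9)

    def test_two_channel_single_state_unrolled(self):
        psi = np.zeros((1, 2, 2))
        psi[0, 0, 1] = 0.9
        psi[0, 1, 0] = -0.9
        R = np.ones((1, 2, 2))
        stats = reconstruct_patterns(
            PhasePatternSet(R=R, psi=psi, R_bar=R.mean(axis=0))
        )
        # the seed pair anchors the higher-index channel at zero, so the
        # pattern is (psi_12, 0): equal to (0, -psi_12) up to global rotation
        np.testing.assert_allclose(stats.patterns[0], [0.9, 0.0], atol=1e-12)
        assert circular_similarity(stats.patterns[0], [0.0, -0.9]) == pytest.approx(1.0)

    def test_channel_permutation_equivariance(self, rng):
        true = rng.uniform(-np.pi, np.pi, 6)
        t = np.linspace(0, 30, 1500)
        theta = wrap_phase(2 * np.pi * t[None, :] + true[:, None])
        labels = StateLabeling(np.ones(1500, dtype=int), K=1)
        perm = rng.permutation(6)
        a = reconstruct_patterns(state_phase_stats(theta, labels)).patterns[0]
        b = reconstruct_patterns(state_phase_stats(theta[perm], labels)).patterns[0]
        assert circular_similarity(a[perm], b) == pytest.approx(1.0, abs=1e-9)

    def test_non_finite_index_rejected(self):
        R = np.full((1, 3, 3), np.nan)
        with pytest.raises(ValueError):
            reconstruct_patterns(PhasePatternSet(R=R, psi=R, R_bar=R[0]))


class TestPpcFromPatterns:
    def test_single_pattern_closed_form(self, rng):
        p = rng.uniform(-np.pi, np.pi, 10)
        C = ppc_from_patterns(p[None, :])
        expected = np.exp(1j * (p[:, None] - p[None, :])) / 10
        np.testing.assert_allclose(C, expected, atol=1e-12)

    def test_projector_identities(self, pattern_set):
        _, _, patterns = pattern_set
        C = ppc_from_patterns(patterns)
        # idempotent
        assert np.linalg.norm(C @ C - C) < 1e-10
        # every embedded pattern is a fixed direction
        for mu in range(patterns.shape[0]):
            p = np.exp(1j * patterns[mu])
            np.testing.assert_allclose(C @ p, p, atol=1e-10)
        # trace equals the rank of the phasor matrix
        assert np.trace(C).real == pytest.approx(3.0, abs=1e-9)
        assert abs(np.trace(C).imag) < 1e-10

    def test_more_patterns_than_channels_rejected(self, rng):
        with pytest.raises(ValueError):
            ppc_from_patterns(rng.uniform(-np.pi, np.pi, (5, 3)))


class TestFluctuationCovariance:
    def test_shared_difference_structure_gives_all_ones(self):
        base = np.array([0.1, 0.7, -1.2, 2.0])
        patterns = np.vstack([base, base + 0.5, base - 1.0])  # common rotations
        Sigma = fluctuation_covariance(patterns)
        np.testing.assert_allclose(Sigma, 1.0, atol=1e-10)

    def test_diagonal_is_one_and_result_psd(self, pattern_set):
        _, _, patterns = pattern_set
        raw = np.abs(
            np.exp(1j * patterns.T) @ np.exp(-1j * patterns.T.conj().T).T.conj().T
        )
        Sigma = fluctuation_covariance(patterns)
        w = np.linalg.eigvalsh(Sigma)
        assert w.min() > -1e-10
        np.testing.assert_allclose(Sigma, Sigma.T, atol=1e-12)

    def test_psd_input_is_fixed_point(self):
        base = np.array([0.0, 0.3])
        Sigma = fluctuation_covariance(base[None, :])
        np.testing.assert_allclose(Sigma, fluctuation_covariance(base[None, :]),
                                   atol=1e-12)
        np.testing.assert_allclose(np.diag(Sigma), 1.0, atol=1e-12)


class TestDwellStatistics:
    def test_hand_enumerated_example(self):
        seq = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3, 1, 1, 2, 2])
        lab = StateLabeling(seq, K=3)
        stats = dwell_statistics(lab, dt=1.0)
        # interior runs: state 2 -> {3}, state 3 -> {3}, state 1 -> {2}
        np.testing.assert_allclose(stats.table[:, 0], [2, 2, 2])
        np.testing.assert_allclose(stats.table[:, 1], [3, 3, 3])
        np.testing.assert_allclose(stats.table[:, 2], [3, 3, 3])

    def test_constant_sequence_rejected(self):
        with pytest.raises(ValueError):
            dwell_statistics(StateLabeling(np.ones(10, dtype=int), K=1), dt=1.0)

    def test_invariant_to_edge_run_lengths(self):
        core = [2, 2, 1, 1, 1, 2, 2, 2, 1]
        a = StateLabeling(np.array([1] * 3 + core + [2] * 7), K=2)
        b = StateLabeling(np.array([1] * 40 + core + [2] * 2), K=2)
        np.testing.assert_allclose(
            dwell_statistics(a, dt=0.5).table, dwell_statistics(b, dt=0.5).table
        )

    def test_seconds_scale_with_dt(self):
        seq = np.array([1, 2, 2, 1, 1, 1, 2])
        lab = StateLabeling(seq, K=2)
        assert dwell_statistics(lab, dt=0.1).table[0, 0] == pytest.approx(
            0.1 * dwell_statistics(lab, dt=1.0).table[0, 0]
        )


class TestEstimateFluctuationLevel:
    @pytest.fixture(scope="class")
    def small_model(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(-np.pi, np.pi, 8)
        patterns = wrap_phase(
            np.vstack([base, base + rng.normal(0, 1.2, 8)])
        )
        C = ppc_from_patterns(patterns)
        model = PPCModel(C_delta=C, omega=2 * np.pi,
                         Sigma=fluctuation_covariance(patterns))
        return model, patterns

    def test_zero_noise_target_estimated_at_zero(self, small_model):
        from metapac.simulator import overlap_labels, simulate_pac

        model, patterns = small_model
        quiet = PPCModel(C_delta=model.C_delta, omega=model.omega,
                         Sigma=model.Sigma, D=0.0)
        # with zero noise every run parks in one basin for the whole window;
        # the target must come from the modal basin for the dwell comparison
        # to be about dwell LENGTH rather than basin identity
        runs = []
        for seed in range(8):
            sim = simulate_pac(quiet, duration=60.0, dt=0.2, seed=seed,
                               with_amplitudes=False, burn_in=60.0)
            _, lab = overlap_labels(sim.phases, patterns)
            runs.append(lab)
        finals = [lab.labels[-1] for lab in runs]
        modal = max(set(finals), key=finals.count)
        lab = runs[finals.index(modal)]
        target = dwell_statistics(lab, dt=0.2, strict=False)
        grid = np.array([0.0, 0.3, 0.6, 0.9])
        D_hat, rmse = estimate_fluctuation_level(
            model, patterns, target, grid=grid, reps=20, duration=60.0,
            dt=0.2, burn_in=60.0, seed=2,
        )
        assert D_hat == 0.0
        assert rmse.shape == (4,)

    def test_estimate_is_grid_member(self, small_model):
        model, patterns = small_model
        target = dwell_statistics(
            StateLabeling(np.array([1, 2, 1, 1, 2, 2, 1] * 30), K=2), dt=0.2
        )
        grid = np.array([0.2, 0.5])
        D_hat, _ = estimate_fluctuation_level(
            model, patterns, target, grid=grid, reps=2, duration=30.0,
            dt=0.2, burn_in=10.0, seed=3,
        )
        assert D_hat in grid

    def test_empty_grid_rejected(self, small_model):
        model, patterns = small_model
        target = dwell_statistics(
            StateLabeling(np.array([1, 2, 1, 2, 2, 1]), K=2), dt=0.2
        )
        with pytest.raises(ValueError):
            estimate_fluctuation_level(model, patterns, target,
                                       grid=np.array([]), reps=1)
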