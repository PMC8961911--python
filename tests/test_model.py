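import numpy as np
import pytest

from onoffseq import (
    InvalidParameterError,
    ModelSpec,
    Params,
    SingularityError,
    assemble_generator,
    build_blocks,
    build_generator,
    stationary_phase_distribution,
)

from conftest import random_params


class TestSpecAndParams:
    def test_free_parameter_count(self):
        assert ModelSpec(L=3).k == 2 + 3 + 1
        assert ModelSpec(L=3, tied_lambdas=True).k == 2 + 1 + 1
        assert ModelSpec(L=2, has_switch=False).k == 2 + 1
        assert ModelSpec(L=2, fixed={"mu": 0.0}).k == 2 + 2

    def test_switch_rates_absent_without_switch(self):
        assert "q_on" not in ModelSpec(L=2, has_switch=False).param_names

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(lambdas=(0.0, 1.0), q_on=0.1, q_off=0.1),
            dict(lambdas=(1.0,), mu=-0.1, q_on=0.1, q_off=0.1),
            dict(lambdas=(1.0,), q_on=-0.5, q_off=0.1),
        ],
    )
    def test_invalid_rates_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            Params(**kwargs)

    def test_params_spec_mismatch_rejected(self):
        p = Params(lambdas=(1.0, 2.0), q_on=0.1, q_off=0.1)
        with pytest.raises(InvalidParameterError):
            p.check_spec(ModelSpec(L=3))
        with pytest.raises(InvalidParameterError):
            p.check_spec(ModelSpec(L=2, has_switch=False))

    def test_invalid_L(self):
        with pytest.raises(InvalidParameterError):
            ModelSpec(L=0)


class TestBlocks:
    def test_birth_block_single_entry(self):
        p = Params(q_on=0.3, q_off=0.7, lambdas=(1.0, 2.0, 3.0), mu=0.0)
        blocks = build_blocks(p, ModelSpec(L=3), C=4)
        for B in blocks.births:
            expected = np.zeros((4, 4))
            expected[3, 1] = 3.0  # lambda_3 at (phase 3 -> phase 1)
            np.testing.assert_array_equal(B, expected)

    def test_death_block_is_m_mu_identity(self):
        p = Params(q_on=0.3, q_off=0.7, lambdas=(1.0, 2.0, 3.0), mu=0.3)
        blocks = build_blocks(p, ModelSpec(L=3), C=3)
        np.testing.assert_allclose(blocks.deaths[1], 0.6 * np.eye(4))

    def test_no_death_block_below_level_zero(self):
        p = Params(q_on=0.3, q_off=0.7, lambdas=(1.0,), mu=0.5)
        blocks = build_blocks(p, ModelSpec(L=1), C=2)
        # deaths[0] belongs to level 1; level 0 has no death block at all
        assert len(blocks.deaths) == 2
        np.testing.assert_allclose(blocks.deaths[0], 0.5 * np.eye(2))

    def test_within_level_matches_displayed_form(self):
        # L=3 within-level block: switch moves 0<->1, lambda_1 and lambda_2
        # advance the phase, the birth row carries nothing within the level
        p = Params(q_on=0.3, q_off=0.7, lambdas=(1.0, 2.0, 3.0), mu=0.0)
        W = build_blocks(p, ModelSpec(L=3), C=2).within_level[0]
        expected = np.array(
            [
                [-0.3, 0.3, 0.0, 0.0],
                [0.7, -1.7, 1.0, 0.0],
                [0.0, 0.0, -2.0, 2.0],
                [0.0, 0.0, 0.0, 0.0],
            ]
        )
        np.testing.assert_allclose(W, expected)


class TestGenerator:
    def test_hand_assembled_L1_C1(self):
        # four states in level-major order: (0,0), (1,0), (0,1), (1,1)
        p = Params(q_on=1.0, q_off=2.0, lambdas=(3.0,), mu=4.0)
        Q = build_generator(p, ModelSpec(L=1), C=1).Q
        expected = np.array(
            [
                [-1.0, 1.0, 0.0, 0.0],
                [2.0, -5.0, 0.0, 3.0],
                [4.0, 0.0, -5.0, 1.0],
                [0.0, 4.0, 2.0, -6.0],
            ]
        )
        np.testing.assert_allclose(Q, expected)

    def test_dimension(self):
        p = Params(q_on=0.1, q_off=0.2, lambdas=(1.0, 1.0, 1.0), mu=0.1)
        gen = build_generator(p, ModelSpec(L=3), C=4)
        assert gen.Q.shape == (20, 20)  # (L+1)(C+1)

    @pytest.mark.parametrize("L,has_switch", [(1, True), (2, True), (3, True), (2, False)])
    def test_conservation_and_positivity(self, rng, L, has_switch):
        for _ in range(5):
            p = random_params(rng, L, has_switch)
            spec = ModelSpec(L=L, has_switch=has_switch)
            Q = build_generator(p, spec, C=7).Q
            assert np.abs(Q.sum(axis=1)).max() < 1e-12 * max(1.0, np.abs(Q).max())
            off = Q - np.diag(np.diag(Q))
            assert off.min() >= 0.0

    def test_block_extraction_roundtrip(self, rng):
        p = random_params(rng, 2)
        spec = ModelSpec(L=2)
        blocks = build_blocks(p, spec, C=5)
        Q = assemble_generator(blocks).Q
        nE = 3
        for m in range(5):
            np.testing.assert_array_equal(
                Q[m * nE:(m + 1) * nE, (m + 1) * nE:(m + 2) * nE], blocks.births[m]
            )
        for m in range(1, 6):
            np.testing.assert_array_equal(
                Q[m * nE:(m + 1) * nE, (m - 1) * nE:m * nE], blocks.deaths[m - 1]
            )
        for m in range(6):
            diag_block = Q[m * nE:(m + 1) * nE, m * nE:(m + 1) * nE]
            W = blocks.within_level[m]
            off_mask = ~np.eye(nE, dtype=bool)
            np.testing.assert_array_equal(diag_block[off_mask], W[off_mask])

    def test_level_C_has_no_birth(self):
        # births are disabled on the last block row: with no deaths the
        # final phase at level C has no exit at all and simply waits
        p = Params(q_on=0.1, q_off=0.2, lambdas=(1.0, 1.0), mu=0.0)
        Q = build_generator(p, ModelSpec(L=2), C=2).Q
        np.testing.assert_array_equal(Q[-1], np.zeros(Q.shape[0]))

    def test_seq_specialization_drops_off_state(self):
        # with q_off = 0 the off-state is unreachable; deleting its rows and
        # columns must reproduce the switchless generator exactly
        lam, mu, C = (1.3, 0.6), 0.4, 4
        p_on = Params(q_on=0.9, q_off=0.0, lambdas=lam, mu=mu)
        p_seq = Params(lambdas=lam, mu=mu)
        Q_on = build_generator(p_on, ModelSpec(L=2), C=C).Q
        Q_seq = build_generator(p_seq, ModelSpec(L=2, has_switch=False), C=C).Q
        keep = [m * 3 + r for m in range(C + 1) for r in (1, 2)]
        np.testing.assert_allclose(Q_on[np.ix_(keep, keep)], Q_seq)


class TestStationaryPhase:
    def test_two_state_balance(self):
        p = Params(q_on=0.1, q_off=0.2, lambdas=(5.0,))
        pi = stationary_phase_distribution(p, ModelSpec(L=1))
        np.testing.assert_allclose(pi, [2 / 3, 1 / 3])

    def test_L3_tied(self):
        p = Params(q_on=0.25, q_off=1.0, lambdas=(10.0,) * 3, mu=2.0)
        pi = stationary_phase_distribution(p, ModelSpec(L=3, tied_lambdas=True))
        np.testing.assert_allclose(pi, [4 / 7, 1 / 7, 1 / 7, 1 / 7])

    def test_seq_cyclic_proportional_to_reciprocal_rates(self):
        p = Params(lambdas=(1.0, 2.0, 4.0))
        pi = stationary_phase_distribution(p, ModelSpec(L=3, has_switch=False))
        w = np.array([1.0, 0.5, 0.25])
        np.testing.assert_allclose(pi, w / w.sum())

    @pytest.mark.parametrize("L,has_switch", [(1, True), (3, True), (3, False)])
    def test_stationarity_identity(self, rng, L, has_switch):
        from onoffseq.model import marginal_phase_generator

        for _ in range(5):
            p = random_params(rng, L, has_switch)
            spec = ModelSpec(L=L, has_switch=has_switch)
            pi = stationary_phase_distribution(p, spec)
            assert pi.min() >= 0 and abs(pi.sum() - 1) < 1e-12
            resid = pi @ marginal_phase_generator(p, spec)
            assert np.abs(resid).max() < 1e-12

    def test_absorbing_off_state_rejected(self):
        p = Params(q_on=0.0, q_off=0.5, lambdas=(1.0,))
        with pytest.raises(SingularityError):
            stationary_phase_distribution(p, ModelSpec(L=1))

    def test_matches_simulated_occupancy(self, rng):
        # long-run fraction of time in the off-state vs pi, 3 MC SEs
        from onoffseq import simulate_path

        p = Params(q_on=0.8, q_off=1.2, lambdas=(2.0, 1.5), mu=0.5)
        spec = ModelSpec(L=2)
        pi = stationary_phase_distribution(p, spec)
        path = simulate_path(p, spec, t_max=4000.0, rng=rng)
        durations = np.diff(np.append(path.times, 4000.0))
        frac_off = durations[path.phases == 0].sum() / 4000.0
        # effective number of off-visits governs the MC error
        n_visits = max((path.phases == 0).sum(), 1)
        se = frac_off / np.sqrt(n_visits)
        assert abs(frac_off - pi[0]) < 3 * se + 1e-3
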