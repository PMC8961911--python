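import numpy as np
import pytest

from onoffseq import (
    ConstraintSet,
    FitResult,
    FitSettings,
    InvalidParameterError,
    ModelSpec,
    Params,
    aic,
    default_candidates,
    fit_mle,
    model_select,
    recovery_study,
    sample_dataset,
)
from onoffseq.inference import _Transform
from onoffseq.simulate import ObservationSet

from conftest import random_params

FAST = FitSettings(starts=1, xatol=3e-4, fatol=1e-3, maxfev=250, ell=256)


def tiny_dataset(seed=5, N=12, n=15):
    spec = ModelSpec(L=2)
    p = Params(q_on=0.5, q_off=0.5, lambdas=(2.0, 1.0), mu=0.3)
    return sample_dataset(p, spec, N=N, lengths=n, rng=seed, x0=1), spec


class TestConstraintSet:
    def test_chain_must_cover_all_lambdas(self):
        with pytest.raises(InvalidParameterError):
            ConstraintSet(order=(1, 3)).check_spec(ModelSpec(L=3))

    def test_chain_meaningless_with_tied(self):
        with pytest.raises(InvalidParameterError):
            ConstraintSet(order=(1, 2)).check_spec(ModelSpec(L=2, tied_lambdas=True))

    def test_satisfied_by(self):
        cs = ConstraintSet(order=(3, 1, 2))
        ok = Params(q_on=1, q_off=1, lambdas=(2.0, 1.0, 3.0))
        bad = Params(q_on=1, q_off=1, lambdas=(2.0, 3.0, 1.0))
        assert cs.satisfied_by(ok)
        assert not cs.satisfied_by(bad)

    def test_describe(self):
        assert ConstraintSet(order=(2, 1)).describe() == "lam_2 >= lam_1"


class TestTransform:
    @pytest.mark.parametrize("chain", [(1, 2, 3), (3, 1, 2), (2, 3, 1)])
    def test_roundtrip_under_chain(self, rng, chain):
        spec = ModelSpec(L=3)
        tr = _Transform(spec, ConstraintSet(order=chain))
        for _ in range(10):
            lams = np.sort(rng.uniform(0.2, 5.0, 3))[::-1]
            values = {"q_on": 0.3, "q_off": 0.9, "mu": 0.1}
            for c, lam in zip(chain, lams):
                values[f"lam_{c}"] = lam
            p = Params.from_dict(spec, values)
            back = tr.to_params(tr.from_params(p))
            np.testing.assert_allclose(back.theta(), p.theta(), rtol=1e-12)

    def test_chain_violation_detected(self):
        spec = ModelSpec(L=2)
        tr = _Transform(spec, ConstraintSet(order=(1, 2)))
        p = Params(q_on=0.1, q_off=0.1, lambdas=(1.0, 2.0))
        with pytest.raises(InvalidParameterError):
            tr.from_params(p)


class TestAic:
    def test_reference_value(self):
        # one free parameter at log-likelihood -3569.9 gives AIC 7141.8
        spec = ModelSpec(L=1, has_switch=False, fixed={"mu": 0.0})
        fit = FitResult(
            params=Params(lambdas=(0.0144,), mu=0.0), spec=spec,
            loglik=-3569.9, aic=2 * 1 - 2 * (-3569.9), k=1,
            constraints=ConstraintSet(), C=50, ell=2048, boundary_hit=False,
            enlargements=0, starts=1, converged=True, n_eval=0,
        )
        assert aic(fit) == pytest.approx(7141.8)
        # excluding the only free parameter leaves -2 logL
        assert aic(fit, exclude=["lam_1"]) == pytest.approx(7139.8)

    def test_extra_parameter_costs_two(self):
        base = dict(
            params=Params(lambdas=(1.0,), q_on=1.0, q_off=1.0), loglik=-100.0,
            constraints=ConstraintSet(), C=10, ell=2048, boundary_hit=False,
            enlargements=0, starts=1, converged=True, n_eval=0,
        )
        f3 = FitResult(spec=ModelSpec(L=1, fixed={"mu": 0.0}), aic=0.0, k=3, **base)
        f4 = FitResult(spec=ModelSpec(L=1), aic=0.0, k=4, **base)
        assert aic(f4) - aic(f3) == pytest.approx(2.0)


class TestFitMle:
    def test_unconstrained_multiphase_refused(self):
        data, spec = tiny_dataset()
        with pytest.raises(InvalidParameterError):
            fit_mle(data, spec, ConstraintSet(), FAST)

    def test_feasibility_and_aic_consistency(self):
        data, spec = tiny_dataset()
        cs = ConstraintSet(order=(1, 2))
        fit = fit_mle(data, spec, cs, FAST)
        assert cs.satisfied_by(fit.params)
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik, abs=1e-9)
        from onoffseq import total_loglik

        recomputed = total_loglik(fit.params, spec, data, C=fit.C, ell=fit.ell).value
        assert recomputed == pytest.approx(fit.loglik, abs=1e-6)

    def test_series_order_invariance(self):
        data, spec = tiny_dataset()
        perm = ObservationSet(series=tuple(reversed(data.series)), delta=data.delta)
        cs = ConstraintSet(order=(1, 2))
        a = fit_mle(data, spec, cs, FAST)
        b = fit_mle(perm, spec, cs, FAST)
        np.testing.assert_allclose(a.params.theta(), b.params.theta(), atol=1e-9)

    def test_boundary_triggers_domain_enlargement(self):
        # data generated with a phase rate far above the initial box bound:
        # the fit must report the boundary hit and recover after doubling
        spec = ModelSpec(L=3, tied_lambdas=True)
        p = Params(q_on=0.25, q_off=1.0, lambdas=(10.0,) * 3, mu=2.0)
        data = sample_dataset(p, spec, N=60, lengths=60, rng=17, x0=1)
        fit = fit_mle(data, spec, ConstraintSet(box_bound=1.0), FAST)
        assert fit.boundary_hit
        assert fit.enlargements >= 1
        assert fit.params.lambdas[0] > 4.0

    def test_truncation_below_data_rejected(self):
        data, spec = tiny_dataset()
        with pytest.raises(InvalidParameterError):
            fit_mle(data, spec, ConstraintSet(order=(1, 2)),
                    FitSettings(C=data.max_count - 1))


class TestModelSelect:
    def test_single_candidate(self):
        data, spec = tiny_dataset()
        cands = [("only", spec, ConstraintSet(order=(1, 2)))]
        results = model_select(data, cands, FAST)
        assert len(results) == 1 and results[0].name == "only"

    def test_failed_candidate_reported_not_fatal(self):
        data, spec = tiny_dataset()
        cands = [
            ("bad", ModelSpec(L=3), ConstraintSet(order=(1, 2))),  # invalid chain
            ("good", ModelSpec(L=1), ConstraintSet()),
        ]
        results = model_select(data, cands, FAST)
        by_name = {r.name: r for r in results}
        assert by_name["bad"].error is not None
        assert by_name["bad"].aic == float("inf")
        assert by_name["good"].error is None

    def test_default_battery_composition(self):
        cands = default_candidates()
        names = [c[0] for c in cands]
        assert names == [
            "seq-1", "seq-2", "seq-3",
            "on/off-seq-1", "on/off-seq-2", "on/off-seq-3",
        ]
        full = default_candidates(full_constraint_battery=True)
        assert len(full) == 12


class TestRecoveryStudy:
    def test_single_replicate_is_simulate_plus_fit(self):
        spec = ModelSpec(L=1)
        p = Params(q_on=0.5, q_off=0.5, lambdas=(1.5,), mu=0.2)
        res = recovery_study(p, spec, ConstraintSet(), n=15, N=10, B=1,
                             seed=3, settings=FAST)
        assert res.estimates.shape[0] == 1
        assert res.n_failed == 0
        assert set(res.summary.index) == {"q_on", "q_off", "lam_1", "mu"}
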