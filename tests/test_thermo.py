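import math

import numpy as np
import pytest

from szcascade import (
    AtpLedger,
    CascadeValidationError,
    InfiniteEntropyError,
    SelectionProbabilities,
    aepr_consistency,
    aepr_from_counts,
    atp_route_consistency,
    beta_recovery_experiment,
    entropy_coding,
    entropy_difference,
    entropy_production_atp,
    entropy_production_step,
    phi_from_selection,
    recover_beta,
    sample_transition_counts,
    solve_channel,
    szilard_work,
    total_work,
)
from szcascade.simulator import TimingProfile
from szcascade.thermo import SignConventionError

LN2 = math.log(2)


class TestSzilardWork:
    def test_one_bit_engine(self):
        """A single measured molecule at 2:1 odds yields kBT ln 2."""
        assert szilard_work(1.0, 2 / 3, 1 / 3, 1.0) == pytest.approx(LN2, abs=1e-15)

    def test_symmetric_code_extracts_nothing(self):
        assert szilard_work(5.0, 0.4, 0.4) == 0.0

    def test_scaling_substitution(self):
        # dXstar=3, p/pstar=e, kBT=2 -> 6
        assert szilard_work(3.0, math.e * 0.2, 0.2, 2.0) == pytest.approx(6.0)

    def test_zero_probability_rejected(self):
        with pytest.raises(InfiniteEntropyError):
            szilard_work(1.0, 1.0, 0.0)

    def test_work_information_identity(self):
        """w/kBT = per-molecule entropy difference = channel step entropy."""
        p, pstar = 0.58, 0.42
        w = szilard_work(1.0, p, pstar, 1.0)
        _, h_info = entropy_difference(SelectionProbabilities(p=p, pstar=pstar, dXstar=1.0))
        h_chan = solve_channel(phi_from_selection(p, pstar)).h_step
        assert w == pytest.approx(h_info, abs=1e-12)
        assert w == pytest.approx(h_chan, abs=1e-9)


class TestTotalWork:
    def test_single_step_reduces_to_szilard(self):
        w, H = total_work([LN2], [1.0], kBT=2.0)
        assert w == pytest.approx(2 * LN2)
        assert H == pytest.approx(LN2)

    def test_additivity_over_identical_steps(self):
        w1, _ = total_work([0.3], [2.0])
        w2, _ = total_work([0.3, 0.3], [2.0, 2.0])
        assert w2 == pytest.approx(2 * w1)

    def test_sum_matches_per_step_recomputation(self, mapk_rest, mapk_spec):
        p = mapk_rest.X_st / mapk_spec.X0
        ps = mapk_rest.Xstar_st / mapk_spec.X0
        h = np.log(p / ps)
        d = np.linspace(0.1, 0.5, mapk_spec.n_steps)
        w_total, _ = total_work(h, d)
        per_step = sum(
            szilard_work(float(d[i]), float(p[i]), float(ps[i]))
            for i in range(mapk_spec.n_steps)
        )
        assert w_total == pytest.approx(per_step)


class TestEntropyCoding:
    def test_probability_from_rate_and_duration(self):
        p, _ = entropy_coding(0.5, [2 * LN2], [-1.0])
        assert p[0] == pytest.approx(0.5)

    def test_noiseless_beta_recovery(self):
        beta = 0.0173
        tau_f = np.array([0.4, 0.5, 0.6, 0.45, 0.55])
        tau_r = -np.array([40.0, 55.0, 60.0, 50.0, 45.0])
        p, ps = entropy_coding(beta, tau_f, tau_r)
        assert abs(recover_beta(p, ps, tau_f, tau_r) - beta) < 1e-10

    def test_zero_beta_flagged_degenerate(self):
        with pytest.raises(SignConventionError, match="beta"):
            entropy_coding(0.0, [1.0], [-1.0])

    def test_wrong_duration_signs_flagged(self):
        with pytest.raises(SignConventionError, match="tau"):
            entropy_coding(0.1, [1.0], [1.0])


class TestAeprFromCounts:
    def test_equal_counts_mean_equilibrium(self):
        assert aepr_from_counts(100, 100, 1.0) == 0.0

    def test_two_to_one_imbalance(self):
        assert aepr_from_counts(200, 100, 1.0) == pytest.approx(LN2)

    def test_duration_scales_the_rate(self):
        assert aepr_from_counts(200, 100, 2.0) == pytest.approx(LN2 / 2)

    def test_zero_counts_regularised(self):
        est = aepr_from_counts(10, 0, 1.0)
        assert np.isfinite(est)
        assert est == pytest.approx(math.log(10.5 / 0.5))

    def test_sampled_estimate_near_analytic_target(self, rng):
        """Binomial cycle sampling recovers log(p/pstar)/(tau - tau_rev)."""
        p, ps = 0.9, 0.5
        tau_f, tau_r = 0.5, -50.0
        target = math.log(p / ps) / (tau_f - tau_r)
        n_fwd, n_rev = sample_transition_counts([p], [ps], 1000, 400, rng)
        est = aepr_from_counts(n_fwd, n_rev, tau_f - tau_r)
        se = est.std(ddof=1) / math.sqrt(est.shape[0])
        assert abs(est.mean() - target) < 3 * se


class TestAeprConsistency:
    def test_single_rate_coding_gives_low_dispersion(self, rng):
        timing = TimingProfile(
            tau_fwd=np.array([0.4, 0.5, 0.6]), tau_rev=-np.array([45.0, 52.0, 60.0])
        )
        p, ps = entropy_coding(0.012, timing.tau_fwd, timing.tau_rev)
        n_fwd, n_rev = sample_transition_counts(p, ps, 1000, 300, rng)
        rep = aepr_consistency(n_fwd, n_rev, timing)
        assert rep.cv < 0.05
        assert rep.beta_hat == pytest.approx(0.012, rel=0.05)
        # sign structure: forward negative, reverse positive, same magnitude
        assert rep.zeta_fwd == -rep.zeta_rev == -rep.beta_hat

    def test_step_dependent_rates_violate_consistency(self, rng):
        """Negative control: a different beta per step inflates the CV."""
        timing = TimingProfile(
            tau_fwd=np.array([0.5, 0.5, 0.5]), tau_rev=-np.array([50.0, 50.0, 50.0])
        )
        betas = np.array([0.004, 0.012, 0.03])
        cols = [
            sample_transition_counts(
                *entropy_coding(b, timing.tau_fwd[i:i + 1], timing.tau_rev[i:i + 1]),
                1000, 300, rng,
            )
            for i, b in enumerate(betas)
        ]
        n_fwd = np.hstack([c[0] for c in cols])
        n_rev = np.hstack([c[1] for c in cols])
        rep = aepr_consistency(n_fwd, n_rev, timing)
        assert rep.cv > 0.3

    def test_single_step_has_undefined_dispersion(self, rng):
        timing = TimingProfile(tau_fwd=np.array([0.5]), tau_rev=np.array([-50.0]))
        n_fwd, n_rev = sample_transition_counts([0.9], [0.5], 1000, 50, rng)
        rep = aepr_consistency(n_fwd, n_rev, timing)
        assert math.isnan(rep.cv)
        assert rep.beta_hat > 0

    def test_full_recovery_pipeline(self):
        res = beta_recovery_experiment(beta=0.01, n_replicates=200, seed=3)
        assert res["relative_error"] < 0.1
        assert res["cv"] < 0.05


class TestEntropyProductionStep:
    def test_no_fluctuation_no_production(self):
        assert entropy_production_step(0.0, 0.0, 1.0, 1.0) == 0.0

    def test_doubling_active_form(self):
        # dX=0, dXstar/Xstar_st=1 -> sigma = ln 2
        assert entropy_production_step(0.0, 1.0, 1.0, 1.0) == pytest.approx(LN2)

    def test_small_fluctuation_linearisation(self):
        """sigma ~ dXstar/Xstar_st - dX/X_st to second order."""
        X_st, Xs_st = 2.0, 1.0
        for eps in (1e-2, 1e-3):
            dXs, dX = eps * Xs_st, -eps * Xs_st
            exact = entropy_production_step(dX, dXs, X_st, Xs_st)
            linear = dXs / Xs_st - dX / X_st
            assert abs(exact - linear) < 2 * (eps ** 2) * (1 + Xs_st / X_st)

    def test_optional_energy_units(self):
        assert entropy_production_step(0.0, 1.0, 1.0, 1.0, kBT=2.0) == pytest.approx(
            2 * LN2
        )

    def test_domain_error_on_nonpositive_ratio(self):
        with pytest.raises(CascadeValidationError, match="nonpositive"):
            entropy_production_step(-2.0, 0.0, 1.0, 1.0)


class TestEntropyProductionAtp:
    def test_untouched_ledger_produces_nothing(self):
        ledger = AtpLedger(A_initial=[1.0, 1.0], A_final=[1.0, 1.0])
        exact, approx = entropy_production_atp(ledger)
        assert exact == 0.0 and approx == 0.0

    def test_two_percent_consumption(self):
        ledger = AtpLedger(A_initial=[100.0], A_final=[98.0])
        exact, approx = entropy_production_atp(ledger)
        assert exact == pytest.approx(-math.log(0.98))
        assert approx == pytest.approx(0.02)

    def test_sequential_ledger_telescopes(self):
        Ai = np.array([100.0, 97.0, 95.0])
        Af = np.array([97.0, 95.0, 92.0])
        exact, _ = entropy_production_atp(AtpLedger(A_initial=Ai, A_final=Af))
        assert exact == pytest.approx(-math.log(92.0 / 100.0))

    def test_ledger_rejects_nonpositive_concentrations(self):
        with pytest.raises(CascadeValidationError):
            AtpLedger(A_initial=[1.0], A_final=[0.0])


class TestRouteConsistency:
    def test_linear_regime_routes_agree(self):
        """Concentration-shift and ATP-ledger entropy production match in
        magnitude when the mediator is drained quasi-statically."""
        res = atp_route_consistency(depletion_fraction=0.015)
        assert res["dA_over_A"] < 0.02
        assert abs(res["magnitude_ratio"] - 1.0) < 0.1
        # linearised ledger form converges on the exact one
        assert res["sigma_atp_approx"] == pytest.approx(
            res["sigma_atp_exact"], rel=0.02
        )
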