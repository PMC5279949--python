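"""d-prime, bias labeling, context effect and the three-predictor GLM."""

import numpy as np
import pytest
from scipy.stats import norm

from conftest import make_sequence
from memtrace import behavior
from memtrace.behavior import (
    BiasLabel, UndefinedMeasureError, build_design_matrix, compute_dprime,
    context_effect, fit_choice_glm, label_bias, prior_estimates,
)
from memtrace.synthetic_data import (
    ObserverParams, generate_decorrelated_sequence, generate_random_sequence,
    simulate_observer,
)


def responses_with_rates(hr, fa, n_pos, n_neg):
    """Response/condition arrays realizing exact HR and FA."""
    truth = np.r_[np.ones(n_pos, bool), np.zeros(n_neg, bool)]
    resp = np.r_[np.arange(n_pos) < round(hr * n_pos),
                 np.arange(n_neg) < round(fa * n_neg)]
    return resp, truth


class TestDprime:
    def test_chance_performance_is_zero(self):
        resp, truth = responses_with_rates(0.5, 0.5, 100, 100)
        assert compute_dprime(resp, truth) == pytest.approx(0.0, abs=1e-12)

    def test_standard_quantile_values(self):
        # Phi^-1(0.8413) = +1, Phi^-1(0.1587) = -1 -> d' = 2
        resp, truth = responses_with_rates(0.8413, 0.1587, 10000, 10000)
        assert compute_dprime(resp, truth) == pytest.approx(2.0, abs=2e-3)

    def test_extreme_rate_correction(self):
        # HR = 1 with N = 20 corrected to 0.975; FA = 0.5 untouched
        resp, truth = responses_with_rates(1.0, 0.5, 20, 20)
        expected = norm.ppf(0.975) - norm.ppf(0.5)
        assert compute_dprime(resp, truth) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(1.96, abs=0.005)

    def test_empty_condition_is_undefined(self):
        with pytest.raises(UndefinedMeasureError):
            compute_dprime(np.array([True, False]), np.array([True, True]))

    def test_antisymmetry_under_relabeling(self):
        rng = np.random.default_rng(2)
        resp = rng.random(300) > 0.35
        truth = rng.random(300) > 0.5
        assert compute_dprime(~resp, truth) == pytest.approx(
            -compute_dprime(resp, truth), abs=1e-12)


class TestPriorEstimates:
    def test_running_mode_arithmetic(self):
        seq = make_sequence([1000, 1100, 900, 1050], [980, 1120, 890, 1030])
        pri = prior_estimates(seq, "running")
        assert pri["global_prior"][3] == pytest.approx(1000.0)
        assert pri["recent_prior"][3] == pytest.approx(900.0)

    def test_exclude_recent_boundary_undefined(self):
        seq = make_sequence([1000, 1100, 900], [980, 1120, 890])
        pri = prior_estimates(seq, "exclude_recent")
        assert np.isnan(pri["global_prior"][1])
        assert pri["global_prior"][2] == pytest.approx(1000.0)

    def test_full_mode_equals_leave_one_out_oracle(self):
        seq = generate_random_sequence(40, seed=8)
        pri = prior_estimates(seq, "full")
        f1 = seq.f1
        oracle = [np.mean(np.delete(f1, i)) for i in range(len(f1))]
        assert np.allclose(pri["global_prior"], oracle)


class TestLabelBias:
    @pytest.mark.parametrize("f1,f2,prior,expected", [
        (1000, 980, 1100, BiasLabel.BIAS_PLUS),
        (1000, 980, 900, BiasLabel.BIAS_MINUS),
        (1000, 1020, 900, BiasLabel.BIAS_PLUS),
        (1000, 1020, 1000, BiasLabel.NEUTRAL),
    ])
    def test_sign_rule(self, f1, f2, prior, expected):
        assert label_bias(f1, f2, prior) is expected

    def test_equal_tones_invalid(self):
        with pytest.raises(ValueError):
            label_bias(1000, 1000, 900)


class TestContextEffect:
    def test_delta_equals_independent_subset_dprimes(self):
        seq = generate_random_sequence(200, seed=4)
        p = ObserverParams(sigma=0.06, w0=0.5, w_floor=0.2, tau_mem=4.0, gamma=0.0)
        choices = simulate_observer(seq, p, seed=4)
        eff = context_effect(seq, choices)
        # independent recomputation from scratch
        f1, f2 = seq.f1, seq.f2
        n = len(f1)
        runmean = np.full(n, np.nan)
        runmean[1:] = np.cumsum(f1)[:-1] / np.arange(1, n)
        lab = np.sign(runmean - f1) * np.sign(f1 - f2)
        parts = {}
        for sgn in (1, -1):
            m = ~np.isnan(lab) & (lab == sgn)
            parts[sgn] = compute_dprime(choices[m], (f1 > f2)[m])
        assert eff.delta_dprime == pytest.approx(parts[1] - parts[-1], abs=1e-12)

    def test_all_one_label_flags_block(self):
        # prior below every f1 and f1 > f2 everywhere -> all BiasMinus
        f1 = np.linspace(2000, 2100, 30)
        seq = make_sequence(f1, f1 * 0.9)
        eff = context_effect(seq, np.ones(30, bool))
        assert not eff.valid

    def test_observed_decay_with_iti(self):
        """A biased observer shows a larger context effect at short than at
        long ITIs in expectation (100 simulated subjects)."""
        p = ObserverParams(sigma=0.055, w0=0.7, w_floor=0.05, tau_mem=3.0,
                           gamma=0.0)
        rng = np.random.default_rng(0)
        short, long_ = [], []
        for _ in range(100):
            for iti, store in ((1.4, short), (8.9, long_)):
                seq = generate_random_sequence(100, iti=iti, seed=rng)
                eff = context_effect(seq, simulate_observer(seq, p, seed=rng))
                if eff.valid:
                    store.append(eff.delta_dprime)
        assert np.mean(short) > np.mean(long_)


class TestDesignMatrix:
    def test_sign_algebra(self):
        # f1=1000, f2=980, global prior 1100 (G=-1) -> c_global = +1
        # recent prior 900 (R=+1) -> c_recent = -1
        seq = make_sequence([1100, 900, 1000], [1105, 905, 980])
        dm = build_design_matrix(seq, [True, True, True], prior_mode="exclude_recent")
        row = dm.iloc[-1]
        assert row["c_global"] == pytest.approx(1.0)   # global prior = 900+1300 / 2 = 1100
        assert row["c_recent"] == pytest.approx(-1.0)
        assert row["x_df"] == pytest.approx(20 / 980 * 100)

    def test_coherence_with_bias_labels(self):
        """c_global = +1 exactly on trials labeled Bias+ from the same prior."""
        seq = generate_random_sequence(150, seed=6)
        choices = np.ones(150, bool)
        dm = build_design_matrix(seq, choices, prior_mode="running")
        pri = prior_estimates(seq, "running")["global_prior"].to_numpy()
        f1, f2 = seq.f1, seq.f2
        labels = [label_bias(f1[i], f2[i], pri[i]) for i in range(1, 150)]
        mapped = np.array([1 if lab is BiasLabel.BIAS_PLUS else -1
                           for lab in labels])
        assert np.array_equal(dm["c_global"].to_numpy(), mapped)


class TestChoiceGlm:
    def _cohort_betas(self, p, n_subjects, seed, trials=150, blocks=2):
        rng = np.random.default_rng(seed)
        fits = []
        for _ in range(n_subjects):
            frames = []
            for _ in range(blocks):
                seq = generate_decorrelated_sequence(trials, seed=rng)
                choices = simulate_observer(seq, p, seed=rng)
                frames.append(build_design_matrix(seq, choices))
            import pandas as pd
            fits.append(fit_choice_glm(pd.concat(frames, ignore_index=True)))
        return fits

    def test_null_observer_has_null_context_betas(self):
        p = ObserverParams(sigma=0.08, w0=0.0, w_floor=0.0, tau_mem=5.0, gamma=0.5)
        fits = self._cohort_betas(p, 20, seed=0)
        for name in ("beta_global", "beta_recent"):
            vals = np.array([getattr(f, name) for f in fits])
            sem = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean()) < 2 * sem + 0.02

    def test_pure_recent_prior_loads_on_recent_beta(self):
        p = ObserverParams(sigma=0.08, w0=0.4, w_floor=0.4, tau_mem=50.0, gamma=1.0)
        fits = self._cohort_betas(p, 12, seed=1)
        b_rec = np.mean([f.beta_recent for f in fits])
        b_glob = np.mean([f.beta_global for f in fits])
        assert b_rec > 0
        assert b_rec > b_glob

    def test_difficulty_beta_null_when_responses_random(self):
        p = ObserverParams(sigma=5.0, w0=0.0, w_floor=0.0, tau_mem=5.0, gamma=0.5)
        fits = self._cohort_betas(p, 12, seed=2)
        vals = np.array([f.beta_df for f in fits])
        sem = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 2 * sem + 0.005

    def test_predictors_decorrelated_on_designed_sequences(self):
        seq = generate_decorrelated_sequence(150, seed=3)
        dm = build_design_matrix(seq, np.ones(150, bool), prior_mode="full")
        corr = np.corrcoef(dm["c_global"], dm["c_recent"])[0, 1]
        assert abs(corr) < 0.1

    def test_too_few_trials_rejected(self):
        seq = generate_random_sequence(20, seed=0)
        dm = build_design_matrix(seq, np.ones(20, bool))
        with pytest.raises(ValueError):
            fit_choice_glm(dm)
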