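import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from oncopass import OmicCohort, SimulationConfig, simulate_cohort
from oncopass.survival import (
    cox_partial_loglik,
    cox_per_gene,
    cox_univariate,
    km_curves,
    stratify_by_cr,
)


def handwritten_partial_loglik(beta, time, event, x):
    """Breslow-free (no ties) Cox partial log-likelihood written from scratch."""
    ll = 0.0
    for i in range(len(time)):
        if event[i]:
            risk = np.exp(beta * x[time >= time[i]])
            ll += beta * x[i] - np.log(risk.sum())
    return ll


class TestCoxUnivariate:
    def eight_subjects(self):
        time = np.array([2.0, 5.0, 7.0, 11.0, 13.0, 17.0, 19.0, 23.0])
        event = np.array([1, 1, 0, 1, 1, 0, 1, 1])
        x = np.array([0.5, -1.2, 0.3, 1.8, -0.7, 0.9, -1.5, 0.2])
        return time, event, x

    def test_matches_brute_force_maximizer(self):
        time, event, x = self.eight_subjects()
        res = cox_univariate(time, event, x)
        oracle = optimize.minimize_scalar(
            lambda b: -handwritten_partial_loglik(b, time, event, x),
            bounds=(-5, 5),
            method="bounded",
            options={"xatol": 1e-10},
        )
        assert res.coefficient == pytest.approx(oracle.x, abs=1e-6)

    def test_matches_lifelines_cross_check(self):
        from lifelines import CoxPHFitter

        time, event, x = self.eight_subjects()
        df = pd.DataFrame({"T": time, "E": event, "x": x})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="T", event_col="E",
                fit_options={"precision": 1e-10})
        res = cox_univariate(time, event, x)
        assert res.coefficient == pytest.approx(cph.params_["x"], abs=1e-6)
        assert res.se == pytest.approx(cph.standard_errors_["x"], rel=1e-4)

    def test_efron_ties_match_lifelines(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(12)
        time = rng.integers(1, 6, size=40).astype(float)  # heavy ties
        event = rng.integers(0, 2, size=40).astype(float)
        event[:10] = 1
        x = rng.normal(size=40)
        df = pd.DataFrame({"T": time, "E": event, "x": x})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="T", event_col="E",
                fit_options={"precision": 1e-10})
        res = cox_univariate(time, event, x)
        assert res.coefficient == pytest.approx(cph.params_["x"], abs=1e-5)

    def test_null_covariate_rarely_extreme(self):
        rng = np.random.default_rng(1)
        n = 200
        time = rng.exponential(1000, n)
        event = (rng.random(n) < 0.7).astype(float)
        x = rng.normal(size=n)
        extreme = 0
        n_perm = 200
        for _ in range(n_perm):
            res = cox_univariate(time, event, rng.permutation(x))
            extreme += abs(res.z_score) >= 3
        assert extreme / n_perm <= 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            cox_univariate(np.arange(1.0, 11.0), np.ones(10), np.ones(10))

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            cox_univariate(np.arange(1.0, 11.0), np.zeros(10), np.arange(10.0))


class TestCoxPerGene:
    def test_planted_hazard_signs_recovered(self):
        agree = total = 0
        for seed in range(5):
            cfg = SimulationConfig(seed=300 + seed, n_samples=250)
            cohort, truth = simulate_cohort(cfg)
            cox = cox_per_gene(cohort, gene_set=pd.Index(truth.outcome_genes))
            for g in cox.index:
                total += 1
                agree += np.sign(cox.loc[g, "z"]) == np.sign(
                    truth.table.loc[g, "hazard_coef"]
                )
        assert agree / total >= 0.9

    def test_requires_events(self):
        cfg = SimulationConfig(seed=2, n_samples=30, n_genes=50, n_chromosomes=1,
                               driver_loci=((0, 25),), censor_rate=0.3)
        cohort, _ = simulate_cohort(cfg)
        cohort.clinical["event"] = 0
        with pytest.raises(ValueError, match="events"):
            cox_per_gene(cohort)


class TestStratifyByCR:
    def test_rho_is_one_when_z_equals_r(self):
        rng = np.random.default_rng(9)
        r = rng.uniform(-1, 1, 100)
        cox = pd.DataFrame({"z": r}, index=[f"G{i}" for i in range(100)])
        cr = pd.DataFrame({"cnv_mrna_r": r}, index=cox.index)
        summary = stratify_by_cr(cox, cr)
        assert summary.spearman_rho == pytest.approx(1.0)

    def test_amplified_poor_group_is_dosage_coupled(self, recovery_sim):
        from oncopass.classify import classify, per_gene_dosage_correlation

        cohort, truth = recovery_sim
        amp = truth.amplicon_genes()
        r = per_gene_dosage_correlation(cohort, gene_set=amp)
        cr = classify(r)
        cox = cox_per_gene(cohort, gene_set=amp)
        summary = stratify_by_cr(cox, cr.table)
        poor, better = summary.groups["poor"], summary.groups["better"]
        assert poor is not None and better is not None
        assert poor["median"] > better["median"]

    def test_reversed_hazard_coefficients_flip_rho(self):
        rhos = []
        for hc_high, hc_low, seed in ((0.8, -0.8, 55), (-0.8, 0.8, 55)):
            cfg = SimulationConfig(
                seed=seed, n_samples=250,
                hazard_coef_crhigh=hc_high, hazard_coef_crlow=hc_low,
            )
            cohort, truth = simulate_cohort(cfg)
            amp = truth.amplicon_genes()
            from oncopass.classify import per_gene_dosage_correlation

            r = per_gene_dosage_correlation(cohort, gene_set=amp)
            cox = cox_per_gene(cohort, gene_set=amp)
            summary = stratify_by_cr(
                cox, pd.DataFrame({"cnv_mrna_r": r})
            )
            rhos.append(summary.spearman_rho)
        assert rhos[0] > 0 > rhos[1]


class TestKaplanMeier:
    def km_cohort(self, time, event, counts):
        n = len(time)
        return OmicCohort(
            expression=pd.DataFrame([counts], index=["GA"], columns=range(n)),
            clinical=pd.DataFrame(
                {"time_days": time, "event": event},
                index=pd.Index(range(n), name="sample"),
            ),
        )

    def test_product_limit_matches_hand_calculation(self):
        # low group: times 1..6, events (1,1,0,1,0,1)
        # S = 5/6, 5/6*4/5=2/3, 2/3*2/3=4/9, 4/9*0=0
        time = np.array([1, 2, 3, 4, 5, 6, 1, 2, 3, 4, 5, 6], float)
        event = np.array([1, 1, 0, 1, 0, 1, 0, 0, 0, 0, 0, 0], float)
        counts = np.array([10.0] * 6 + [1000.0] * 6)
        curves, chi2, p = km_curves(self.km_cohort(time, event, counts), "GA")
        low = curves["low"].set_index("time")["survival"]
        assert low.loc[1.0] == pytest.approx(5 / 6)
        assert low.loc[2.0] == pytest.approx(2 / 3)
        assert low.loc[4.0] == pytest.approx(4 / 9)
        assert low.loc[6.0] == pytest.approx(0.0)

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(10)
        time = np.concatenate([rng.exponential(10, 8), rng.exponential(10, 8)])
        event = np.ones(16)
        counts = np.array([10.0] * 8 + [1000.0] * 8)
        curves, _, _ = km_curves(self.km_cohort(time, event, counts), "GA")
        low_t = np.sort(time[:8])
        low = curves["low"].set_index("time")["survival"]
        for k, t in enumerate(low_t):
            assert low.loc[t] == pytest.approx(1 - (k + 1) / 8)

    def test_all_censored_flat_and_flagged(self):
        time = np.arange(1.0, 13.0)
        event = np.zeros(12)
        counts = np.array([10.0] * 6 + [1000.0] * 6)
        curves, chi2, p = km_curves(self.km_cohort(time, event, counts), "GA")
        for c in curves.values():
            assert (c["survival"] == 1.0).all()
        assert np.isnan(chi2)

    def test_identical_outcomes_logrank_zero(self):
        time = np.array([1, 2, 3, 4, 5, 6] * 2, float)
        event = np.array([1, 1, 0, 1, 0, 1] * 2, float)
        counts = np.array([10.0] * 6 + [1000.0] * 6)
        _, chi2, _ = km_curves(self.km_cohort(time, event, counts), "GA")
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_tertile_split_makes_three_groups(self):
        time = np.arange(1.0, 16.0)
        event = np.ones(15)
        counts = np.arange(15, dtype=float) * 10 + 1
        curves, chi2, _ = km_curves(
            self.km_cohort(time, event, counts), "GA", split="tertile"
        )
        assert set(curves) == {"low", "medium", "high"}
        assert np.isfinite(chi2)

    def test_degenerate_split_rejected(self):
        time = np.arange(1.0, 9.0)
        event = np.ones(8)
        counts = np.full(8, 10.0)  # all identical -> one group
        with pytest.raises(ValueError, match="split"):
            km_curves(self.km_cohort(time, event, counts), "GA")
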