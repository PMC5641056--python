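from math import comb

import numpy as np
import pandas as pd
import pytest

from oncopass import OmicCohort, SimulationConfig, simulate_cohort
from oncopass.methylation import (
    beta_gain_vs_2N,
    cnv_methylation_correlation,
    coherence,
)


def meth_cohort(betas, cnv_row, probe_map=None):
    n = len(cnv_row)
    genes = list(dict.fromkeys((probe_map or {"cg1": "GA"}).values()))
    if probe_map is None:
        probe_map = {"cg1": "GA"}
    return OmicCohort(
        cnv=pd.DataFrame([cnv_row] * len(genes), index=genes, columns=range(n)),
        methylation=pd.DataFrame(betas, index=list(probe_map), columns=range(n)),
        probe_map=pd.DataFrame(
            {"probe": list(probe_map), "gene": list(probe_map.values())}
        ),
    )


class TestCnvMethylationCorrelation:
    def test_monotone_coupling_is_near_one(self):
        rng = np.random.default_rng(0)
        cnv = rng.normal(0, 0.5, 40)
        beta = np.clip(0.1 + 0.3 * cnv, 0.01, 0.99)
        cohort = meth_cohort([beta], cnv)
        tab = cnv_methylation_correlation(cohort).table
        assert tab.loc["GA", "cnv_meth_r"] > 0.9  # clamping at the beta floor costs a little

    def test_matches_direct_pearson(self):
        rng = np.random.default_rng(1)
        cnv = rng.normal(0, 0.5, 20)
        beta = np.clip(rng.beta(2, 2, 20), 0.01, 0.99)
        cohort = meth_cohort([beta], cnv)
        tab = cnv_methylation_correlation(cohort).table
        want = np.corrcoef(cnv, beta)[0, 1]
        assert tab.loc["GA", "cnv_meth_r"] == pytest.approx(want, abs=1e-12)

    def test_constant_beta_excluded(self):
        rng = np.random.default_rng(2)
        cohort = meth_cohort([np.full(20, 0.5)], rng.normal(0, 0.5, 20))
        tab = cnv_methylation_correlation(cohort).table
        assert "GA" not in tab.index

    def test_probe_policies_agree_for_single_probe(self):
        rng = np.random.default_rng(3)
        cnv = rng.normal(0, 0.5, 30)
        beta = np.clip(0.3 + 0.2 * cnv + rng.normal(0, 0.05, 30), 0.01, 0.99)
        cohort = meth_cohort([beta], cnv)
        best = cnv_methylation_correlation(cohort, probe_policy="best_abs").table
        mean = cnv_methylation_correlation(cohort, probe_policy="mean_beta").table
        assert best.loc["GA", "cnv_meth_r"] == mean.loc["GA", "cnv_meth_r"]

    def test_best_abs_selects_strongest_probe(self):
        rng = np.random.default_rng(4)
        cnv = rng.normal(0, 0.5, 30)
        strong = np.clip(0.3 + 0.3 * cnv, 0.01, 0.99)
        weak = np.clip(rng.beta(2, 2, 30), 0.01, 0.99)
        cohort = meth_cohort(
            [weak, strong], cnv, probe_map={"cg_w": "GA", "cg_s": "GA"}
        )
        tab = cnv_methylation_correlation(cohort, probe_policy="best_abs").table
        assert tab.loc["GA", "best_probe"] == "cg_s"
        assert tab.loc["GA", "n_probes"] == 2


class TestCoherence:
    def test_exact_negative_identity(self):
        rng = np.random.default_rng(5)
        mrna = pd.Series(rng.normal(0.4, 0.3, 50))
        rho, slope = coherence(-mrna, mrna)
        assert rho == pytest.approx(-1.0)
        assert slope == pytest.approx(-1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(6)
        a = pd.Series(rng.normal(size=1000))
        b = pd.Series(rng.normal(size=1000))
        rho, _ = coherence(a, b)
        assert abs(rho) < 0.1

    def test_compensated_simulation_gives_negative_rho(self, recovery_sim):
        cohort, truth = recovery_sim
        amp = truth.amplicon_genes()
        from oncopass.classify import per_gene_dosage_correlation

        mrna_r = per_gene_dosage_correlation(cohort, gene_set=amp)
        meth = cnv_methylation_correlation(cohort, gene_set=amp)
        rho, slope = coherence(meth.table["cnv_meth_r"], mrna_r)
        assert rho < 0
        assert slope < 0

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            coherence(pd.Series([0.1] * 5), pd.Series([0.2] * 5))


class TestBetaGainVs2N:
    def separated_cohort(self):
        # 10 gain samples with betas near 0.8, 10 neutral near 0.2; no ties
        betas = np.concatenate(
            [0.8 + np.arange(10) * 1e-3, 0.2 + np.arange(10) * 1e-3]
        )
        cnv = np.array([0.9] * 10 + [0.0] * 10)
        return meth_cohort([betas], cnv)

    def test_fully_separated_groups_exact_p(self):
        res = beta_gain_vs_2N(self.separated_cohort(), "GA")
        assert res.direction == "hyper"
        # perfectly separated ranks: two-sided exact p = 2 / C(20, 10)
        assert res.p_value == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_identical_distributions_give_none(self):
        rng = np.random.default_rng(7)
        betas = rng.beta(2, 2, 40)
        cnv = np.array([0.9] * 20 + [0.0] * 20)
        res = beta_gain_vs_2N(meth_cohort([betas], cnv), "GA")
        assert res.direction == "none"

    def test_small_group_rejected(self):
        betas = np.linspace(0.1, 0.9, 13)
        cnv = np.array([0.9] * 3 + [0.0] * 10)
        with pytest.raises(ValueError, match="group"):
            beta_gain_vs_2N(meth_cohort([betas], cnv), "GA")

    def test_loss_side_uses_deleted_samples(self):
        betas = np.concatenate(
            [0.1 + np.arange(10) * 1e-3, 0.6 + np.arange(10) * 1e-3]
        )
        cnv = np.array([-0.9] * 10 + [0.0] * 10)
        res = beta_gain_vs_2N(meth_cohort([betas], cnv), "GA", side="loss")
        assert res.direction == "hypo"


class TestCoherenceSignAcrossSeeds:
    def test_sign_recovery_over_seeds(self):
        from oncopass.classify import per_gene_dosage_correlation

        negative = 0
        n_seeds = 8
        for seed in range(n_seeds):
            cfg = SimulationConfig(
                seed=200 + seed, n_samples=150, n_genes=600, n_chromosomes=3,
                driver_loci=((0, 100),), methyl_compensation=1.0,
            )
            cohort, truth = simulate_cohort(cfg)
            amp = truth.amplicon_genes()
            mrna_r = per_gene_dosage_correlation(cohort, gene_set=amp)
            meth = cnv_methylation_correlation(cohort, gene_set=amp)
            rho, _ = coherence(meth.table["cnv_meth_r"], mrna_r)
            negative += rho < 0
        assert negative == n_seeds
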