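"""Instrument selection, harmonization and the five MR estimators."""

import numpy as np
import pandas as pd
import pytest

from signalmr.mr import (
    InstrumentSet, MRModel, PositiveControlError, harmonize, ivw,
    mode_estimators, mr_egger, positive_control, select_instruments,
    weighted_median,
)
from signalmr.synthetic import GwasSimConfig, simulate_gwas_pair


def _gwas_df(rows):
    return pd.DataFrame(rows, columns=["SNP", "CHR", "POS", "EA", "OA",
                                       "EAF", "BETA", "SE", "P"])


def _ld(snps, r2=None):
    m = np.eye(len(snps))
    if r2:
        for (i, j), v in r2.items():
            m[i, j] = m[j, i] = np.sqrt(v)
    return pd.DataFrame(m, index=snps, columns=snps)


class TestClumping:
    def test_no_ld_keeps_all(self):
        df = _gwas_df([(f"rs{i}", "1", 1000 + i * 100, "A", "G", 0.3, 0.1,
                        0.01, 1e-10) for i in range(5)])
        kept = select_instruments(df, ("1", 0, 10_000), _ld(list(df.SNP)))
        assert len(kept) == 5

    def test_correlated_neighbour_clumped(self):
        # hand-traced greedy rule: best p wins, r2=0.5 neighbour discarded
        df = _gwas_df([("rs1", "1", 1000, "A", "G", 0.3, 0.12, 0.01, 1e-12),
                       ("rs2", "1", 1500, "A", "G", 0.3, 0.10, 0.01, 1e-9)])
        ld = _ld(["rs1", "rs2"], {(0, 1): 0.5})
        kept = select_instruments(df, ("1", 0, 10_000), ld)
        assert kept == ["rs1"]

    def test_outside_window_retained_despite_ld(self):
        # third SNP 200 kb away with r2=0.9: outside the 100 kb window
        df = _gwas_df([("rs1", "1", 1000, "A", "G", 0.3, 0.12, 0.01, 1e-12),
                       ("rs2", "1", 1500, "A", "G", 0.3, 0.10, 0.01, 1e-9),
                       ("rs3", "1", 201_000, "A", "G", 0.3, 0.08, 0.01, 1e-8 / 2)])
        ld = _ld(["rs1", "rs2", "rs3"], {(0, 1): 0.5, (0, 2): 0.9})
        kept = select_instruments(df, ("1", 0, 300_000), ld)
        assert kept == ["rs1", "rs3"]

    def test_region_and_p_filters(self):
        df = _gwas_df([("rs1", "1", 1000, "A", "G", 0.3, 0.1, 0.01, 1e-12),
                       ("rs2", "1", 99_000, "A", "G", 0.3, 0.1, 0.01, 1e-12),
                       ("rs3", "1", 2000, "A", "G", 0.3, 0.02, 0.01, 0.04)])
        kept = select_instruments(df, ("1", 0, 50_000),
                                  _ld(["rs1", "rs2", "rs3"]))
        assert kept == ["rs1"]

    def test_empty_selection_errors(self):
        df = _gwas_df([("rs1", "1", 1000, "A", "G", 0.3, 0.1, 0.01, 0.5)])
        with pytest.raises(ValueError, match="no instruments"):
            select_instruments(df, ("1", 0, 10_000), _ld(["rs1"]))


class TestHarmonize:
    exp = _gwas_df([("rs1", "1", 1, "A", "G", 0.3, 0.10, 0.01, 1e-10),
                    ("rs2", "1", 2, "C", "T", 0.2, 0.08, 0.01, 1e-10),
                    ("rs3", "1", 3, "A", "T", 0.20, 0.09, 0.01, 1e-10),
                    ("rs4", "1", 4, "A", "T", 0.50, 0.07, 0.01, 1e-10)])

    def test_swapped_alleles_flip_sign(self):
        out = _gwas_df([("rs1", "1", 1, "G", "A", 0.7, 0.05, 0.02, 1e-4)])
        inst = harmonize(self.exp, out)
        assert inst.snps == ["rs1"]
        assert inst.beta_y[0] == pytest.approx(-0.05)

    def test_strand_flip_no_sign_change(self):
        # exposure C/T, outcome G/A with matching frequency
        out = _gwas_df([("rs2", "1", 2, "G", "A", 0.2, 0.04, 0.02, 1e-4)])
        inst = harmonize(self.exp, out)
        assert inst.beta_y[0] == pytest.approx(0.04)

    def test_palindromic_ambiguous_dropped(self):
        out = _gwas_df([("rs4", "1", 4, "A", "T", 0.50, 0.04, 0.02, 1e-4),
                        ("rs1", "1", 1, "A", "G", 0.3, 0.05, 0.02, 1e-4)])
        inst = harmonize(self.exp, out)
        assert inst.snps == ["rs1"]
        assert any("ambiguous" in line for line in inst.log)

    def test_palindromic_resolved_by_frequency(self):
        # A/T with EAF 0.2 both sides: retained, aligned
        out = _gwas_df([("rs3", "1", 3, "A", "T", 0.2, 0.04, 0.02, 1e-4)])
        inst = harmonize(self.exp, out)
        assert inst.snps == ["rs3"]
        assert inst.beta_y[0] == pytest.approx(0.04)

    def test_irreconcilable_dropped_with_reason(self):
        out = _gwas_df([("rs1", "1", 1, "A", "C", 0.3, 0.04, 0.02, 1e-4),
                        ("rs2", "1", 2, "C", "T", 0.2, 0.04, 0.02, 1e-4)])
        inst = harmonize(self.exp, out)
        assert inst.snps == ["rs2"]
        assert any("irreconcilable" in line for line in inst.log)

    def test_all_dropped_raises(self):
        out = _gwas_df([("rs1", "1", 1, "A", "C", 0.3, 0.04, 0.02, 1e-4)])
        with pytest.raises(ValueError, match="every SNP"):
            harmonize(self.exp, out)

    def test_orientation_makes_beta_x_positive(self):
        exp = _gwas_df([("rs1", "1", 1, "A", "G", 0.3, -0.10, 0.01, 1e-10),
                        ("rs2", "1", 2, "C", "T", 0.2, 0.08, 0.01, 1e-10)])
        out = _gwas_df([("rs1", "1", 1, "A", "G", 0.3, -0.06, 0.02, 1e-4),
                        ("rs2", "1", 2, "C", "T", 0.2, 0.05, 0.02, 1e-4)])
        inst = harmonize(exp, out)
        assert np.all(inst.beta_x > 0)
        assert inst.beta_y[inst.snps.index("rs1")] == pytest.approx(0.06)


def _inst(bx, by, se_y, se_x=None, snps=None):
    bx = np.asarray(bx, float)
    se_x = np.full_like(bx, 1e-6) if se_x is None else np.asarray(se_x, float)
    snps = snps or [f"rs{i:03d}" for i in range(len(bx))]
    return InstrumentSet(snps, bx, se_x, np.asarray(by, float),
                         np.asarray(se_y, float))


class TestIvw:
    def test_collinear_exact(self):
        r = ivw(_inst([0.1, 0.2], [0.05, 0.10], [0.01, 0.01]))
        assert r.beta == pytest.approx(0.5)
        assert r.q == pytest.approx(0.0)

    def test_matches_wls_oracle(self):
        import statsmodels.api as sm

        bx = [0.1, 0.15, 0.3]
        by = [0.07, 0.05, 0.2]
        sy = [0.01, 0.02, 0.015]
        r = ivw(_inst(bx, by, sy))
        fit = sm.WLS(by, np.asarray(bx)[:, None],
                     weights=1 / np.asarray(sy) ** 2).fit()
        assert r.beta == pytest.approx(fit.params[0], abs=1e-10)

    def test_requires_two_snps(self):
        with pytest.raises(ValueError):
            ivw(_inst([0.1], [0.05], [0.01]))

    def test_random_effects_never_deflate(self):
        # perfectly collinear data: Q=0, but the fixed-effect SE is kept
        r = ivw(_inst([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], [0.01] * 3))
        fixed_se = 1 / np.sqrt(np.sum(np.array([0.1, 0.2, 0.3]) ** 2) / 0.01**2)
        assert r.se == pytest.approx(fixed_se)


class TestEgger:
    def test_exact_proportionality(self):
        bx = np.array([0.1, 0.2, 0.3, 0.15])
        r = mr_egger(_inst(bx, 0.7 * bx, [0.01] * 4))
        assert r.beta == pytest.approx(0.7)
        assert r.intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_lands_in_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.15, 0.25])
        r = mr_egger(_inst(bx, 0.7 * bx + 0.02, [0.01] * 5))
        assert r.intercept == pytest.approx(0.02)
        assert r.beta == pytest.approx(0.7)

    def test_matches_statsmodels_wls(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        bx = rng.uniform(0.05, 0.3, 8)
        by = 0.4 * bx + rng.normal(0, 0.05, 8)
        sy = rng.uniform(0.01, 0.03, 8)
        r = mr_egger(_inst(bx, by, sy))
        X = sm.add_constant(bx)
        fit = sm.WLS(by, X, weights=1 / sy**2).fit()
        assert r.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert r.intercept == pytest.approx(fit.params[0], abs=1e-10)
        if fit.scale > 1:  # same residual scaling regime
            assert r.se == pytest.approx(fit.bse[1], abs=1e-10)

    def test_requires_three_snps(self):
        with pytest.raises(ValueError):
            mr_egger(_inst([0.1, 0.2], [0.05, 0.1], [0.01, 0.01]))


class TestWeightedMedian:
    def test_all_ratios_equal(self):
        bx = np.array([0.1, 0.2, 0.3])
        r = weighted_median(_inst(bx, 0.5 * bx, [0.01] * 3), n_boot=50, seed=1)
        assert r.beta == pytest.approx(0.5)

    def test_hand_computed_interpolation(self):
        # ratios [0.8, 1.0, 1.2, 2.0, 3.0], weights [1, 2, 2, 3, 1]:
        # cumulative (S_j - w_j/2)/S puts 0.5 between the 3rd and 4th ratio,
        # fraction 0.2 of the gap -> 1.36
        theta = np.array([0.8, 1.0, 1.2, 2.0, 3.0])
        w = np.array([1.0, 2.0, 2.0, 3.0, 1.0])
        bx = np.ones(5)
        se_y = 1 / np.sqrt(w)
        r = weighted_median(_inst(bx, theta, se_y), n_boot=50, seed=1)
        assert r.beta == pytest.approx(1.36, abs=1e-12)

    def test_robust_to_30pct_contamination(self):
        rng = np.random.default_rng(3)
        L = 30
        bx = rng.uniform(0.1, 0.3, L)
        se_y = np.full(L, 0.002)
        by = 0.5 * bx + rng.normal(0, se_y)
        by[:9] += 0.08  # 30% of instruments strongly pleiotropic
        inst = _inst(bx, by, se_y)
        wm = weighted_median(inst, n_boot=100, seed=2)
        iv = ivw(inst)
        assert abs(wm.beta - 0.5) < abs(iv.beta - 0.5)


class TestModes:
    def test_all_ratios_equal_degenerate_bandwidth(self):
        bx = np.array([0.1, 0.2, 0.4])
        simple, weighted = mode_estimators(_inst(bx, 0.8 * bx, [0.01] * 3),
                                           n_boot=50, seed=4)
        assert simple.beta == pytest.approx(0.8)
        assert weighted.beta == pytest.approx(0.8)

    def test_bimodal_majority_cluster_wins(self):
        bx = np.ones(10) * 0.2
        theta = np.array([0.5] * 7 + [2.0] * 3) + np.linspace(-0.01, 0.01, 10)
        simple, weighted = mode_estimators(_inst(bx, theta * bx, [0.01] * 10),
                                           n_boot=50, seed=5)
        assert simple.beta == pytest.approx(0.5, abs=0.15)
        assert weighted.beta == pytest.approx(0.5, abs=0.15)

    def test_bandwidth_scaling_is_smooth(self, instruments):
        m1 = mode_estimators(instruments, bandwidth_phi=1.0, n_boot=30, seed=6)
        m2 = mode_estimators(instruments, bandwidth_phi=2.0, n_boot=30, seed=6)
        assert abs(m1[0].beta - m2[0].beta) < 0.2


class TestInvariances:
    def test_permutation_invariance_all_estimators(self, instruments):
        res1 = MRModel(instruments, n_boot=100).fit(seed=9)
        perm = np.random.default_rng(0).permutation(len(instruments))
        shuffled = InstrumentSet(
            [instruments.snps[i] for i in perm], instruments.beta_x[perm],
            instruments.se_x[perm], instruments.beta_y[perm],
            instruments.se_y[perm])
        res2 = MRModel(shuffled, n_boot=100).fit(seed=9)
        for r1, r2 in zip(res1, res2):
            assert r1.beta == r2.beta
            assert r1.se == r2.se

    def test_scale_invariance_of_ratio(self, instruments):
        res1 = MRModel(instruments, n_boot=50).fit(seed=3)
        scaled = InstrumentSet(instruments.snps, instruments.beta_x * 3,
                               instruments.se_x * 3, instruments.beta_y * 3,
                               instruments.se_y * 3)
        res2 = MRModel(scaled, n_boot=50).fit(seed=3)
        for r1, r2 in zip(res1, res2):
            assert r1.beta == pytest.approx(r2.beta, rel=1e-9)

    def test_or_ci_exp_consistency(self, instruments):
        for r in MRModel(instruments, n_boot=50).fit(seed=1):
            assert r.or_hat == pytest.approx(np.exp(r.beta))
            assert r.ci_low == pytest.approx(
                np.exp(r.beta - 1.959963984540054 * r.se))

    def test_estimators_agree_without_pleiotropy(self):
        sim = simulate_gwas_pair(GwasSimConfig(
            n_snps=150, causal_theta=0.3, seed=13, swap_fraction=0,
            strand_flip_fraction=0, palindromic_fraction=0))
        inst = harmonize(sim.exposure, sim.outcome)
        res = MRModel(inst, n_boot=200).fit(seed=1)
        betas = [r.beta for r in res]
        assert np.ptp(betas) < 0.02
        assert np.allclose(betas, 0.3, atol=0.02)


class TestPositiveControl:
    def _protective_inst(self, seed=21):
        sim = simulate_gwas_pair(GwasSimConfig(n_snps=60, causal_theta=-0.65,
                                               seed=seed))
        return harmonize(sim.exposure, sim.outcome)

    def test_protective_truth_validates(self):
        res = positive_control(self._protective_inst(), "protective",
                               n_boot=100, seed=1)
        assert res["IVW"].or_hat < 1
        assert res["IVW"].pval < 0.05

    def test_wrong_direction_is_hard_error(self):
        with pytest.raises(PositiveControlError):
            positive_control(self._protective_inst(), "risk",
                             n_boot=100, seed=1)

    def test_null_truth_warns_not_asserts(self):
        with pytest.warns(UserWarning, match="direction"):
            positive_control(self._protective_inst(), None,
                             n_boot=100, seed=1)
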