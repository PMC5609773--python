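"""Instrument alignment, GRS, TSLS, IVW, MR-Egger, KS enrichment, funnel
data and the MR power calculator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from triplemr import mr
from triplemr.io import SummaryStatsTable
from conftest import make_gm


def make_sumstats(snp_ids, betas, ses=None, eaf=0.3, effect="G", other="A"):
    n = len(snp_ids)
    return SummaryStatsTable(
        pd.DataFrame(
            {
                "snp_id": snp_ids,
                "effect_allele": effect,
                "other_allele": other,
                "beta": betas,
                "se": ses if ses is not None else np.full(n, 0.02),
                "p": 1e-8,
                "eaf": eaf,
            }
        )
    )


def make_instrument_set(bx, by, se_y, maf=None):
    m = len(bx)
    return mr.InstrumentSet(
        snp_ids=[f"rs{i}" for i in range(m)],
        exposure_betas=bx,
        exposure_ses=np.full(m, 0.01),
        outcome_betas=by,
        outcome_ses=se_y,
        maf=maf if maf is not None else np.full(m, 0.3),
    )


class TestGrs:
    def test_single_snp_unit_weight_is_dosage(self, rng):
        dos = rng.choice([0.0, 1.0, 2.0], size=(30, 1), p=[0.5, 0.4, 0.1])
        gm = make_gm(dos)  # counted allele is alt = G
        ss = make_sumstats(["v0"], [1.0])
        np.testing.assert_allclose(mr.grs(gm, ss), dos[:, 0])

    def test_zero_weights_zero_score(self, rng):
        dos = rng.choice([0.0, 1.0, 2.0], size=(20, 3))
        gm = make_gm(dos)
        ss = make_sumstats(["v0", "v1", "v2"], [0.0, 0.0, 0.0])
        np.testing.assert_allclose(mr.grs(gm, ss), 0.0)

    def test_allele_flip_reproduces_score(self, rng):
        """Summary rows written against the opposite allele are re-oriented
        to the counted allele and give the identical score."""
        dos = rng.choice([0.0, 1.0, 2.0], size=(25, 2), p=[0.5, 0.4, 0.1])
        gm = make_gm(dos)
        betas = np.array([0.3, -0.2])
        ss = make_sumstats(["v0", "v1"], betas)
        flipped = make_sumstats(["v0", "v1"], -betas, eaf=0.7, effect="A", other="G")
        np.testing.assert_allclose(mr.grs(gm, ss), mr.grs(gm, flipped), atol=1e-12)

    def test_missing_dosage_expected_value(self):
        dos = np.array([[1.0], [np.nan]])
        gm = make_gm(dos)
        ss = make_sumstats(["v0"], [2.0], eaf=0.25)
        np.testing.assert_allclose(mr.grs(gm, ss), [2.0, 2 * 0.25 * 2.0])

    def test_unmatched_alleles_error(self, rng):
        gm = make_gm(rng.choice([0.0, 1.0], size=(10, 1)))
        ss = make_sumstats(["v0"], [0.1], effect="T", other="C")
        with pytest.raises(ValueError, match="unmatched"):
            mr.grs(gm, ss)


class TestTsls:
    def test_single_instrument_equals_wald_ratio(self, rng):
        n = 500
        z = rng.choice([0.0, 1.0, 2.0], n, p=[0.4, 0.4, 0.2])
        x = 0.3 * z + rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        res = mr.tsls(x, y, z[:, None])
        wald = np.cov(z, y)[0, 1] / np.cov(z, x)[0, 1]
        assert res.beta == pytest.approx(wald, abs=1e-10)

    def test_beats_confounded_ols(self):
        """Under a strong unmeasured confounder, TSLS stays consistent
        while naive OLS is biased."""
        cover, ols_bias, tsls_bias = 0, [], []
        for rep in range(25):
            rng = np.random.default_rng(100 + rep)
            n, m = 3000, 16
            Z = rng.choice([0.0, 1.0, 2.0], size=(n, m), p=[0.49, 0.42, 0.09])
            u = rng.standard_normal(n)
            x = Z @ rng.uniform(0.1, 0.2, m) + u + rng.standard_normal(n)
            y = 0.3 * x + 1.2 * u + rng.standard_normal(n)
            res = mr.tsls(x, y, Z)
            lo, hi = res.beta - 1.96 * res.se, res.beta + 1.96 * res.se
            cover += lo <= 0.3 <= hi
            b_ols = np.cov(x, y)[0, 1] / np.var(x)
            ols_bias.append(abs(b_ols - 0.3))
            tsls_bias.append(abs(res.beta - 0.3))
        assert cover >= 20
        assert np.mean(ols_bias) > 2 * np.mean(tsls_bias)

    def test_grs_and_multi_instrument_agree(self, rng):
        n, m = 4000, 16
        Z = rng.choice([0.0, 1.0, 2.0], size=(n, m), p=[0.49, 0.42, 0.09])
        w = rng.uniform(0.05, 0.15, m)
        x = Z @ w + rng.standard_normal(n)
        y = 0.25 * x + rng.standard_normal(n)
        multi = mr.tsls(x, y, Z)
        single = mr.tsls(x, y, (Z @ w)[:, None])
        joint_se = np.hypot(multi.se, single.se)
        assert abs(multi.beta - single.beta) < joint_se

    def test_no_instrument_strength_errors(self, rng):
        x = rng.standard_normal(100)
        y = rng.standard_normal(100)
        with pytest.raises(ValueError, match="instrument strength"):
            mr.tsls(x, y, np.zeros((100, 2)) + 1.0)

    def test_weak_instrument_warns(self, rng):
        n = 300
        z = rng.choice([0.0, 1.0], n)
        x = 0.02 * z + rng.standard_normal(n)
        y = rng.standard_normal(n)
        with pytest.warns(UserWarning, match="weak instruments"):
            mr.tsls(x, y, z[:, None])


class TestExclusionCheck:
    def test_valid_instruments_mostly_pass(self, rng):
        n, m = 2000, 16
        Z = rng.choice([0.0, 1.0, 2.0], size=(n, m))
        x = Z @ rng.uniform(0.05, 0.15, m) + rng.standard_normal(n)
        y = 0.3 * x + rng.standard_normal(n)
        out = mr.instrument_exclusion_check(Z, x, y)
        assert out["pass"].mean() >= 0.8

    def test_pleiotropic_instrument_fails(self, rng):
        n = 5000
        z = rng.choice([0.0, 1.0, 2.0], n)
        x = 0.3 * z + rng.standard_normal(n)
        y = 0.3 * x + 0.3 * z + rng.standard_normal(n)  # direct path z -> y
        out = mr.instrument_exclusion_check(z[:, None], x, y)
        assert not out.loc[0, "pass"]

    def test_independent_outcome_all_pass(self, rng):
        n, m = 1000, 8
        Z = rng.choice([0.0, 1.0, 2.0], size=(n, m))
        x = rng.standard_normal(n) + Z @ np.full(m, 0.2)
        y = rng.standard_normal(n)
        out = mr.instrument_exclusion_check(Z, x, y, alpha=0.001)
        assert out["pass"].all()


class TestIvw:
    def test_single_instrument_wald(self):
        s = make_instrument_set(np.array([0.2]), np.array([0.05]), np.array([0.01]))
        res = mr.ivw(s)
        assert res.beta == pytest.approx(0.05 / 0.2)
        assert res.se == pytest.approx(0.01 / 0.2)

    def test_equal_ratios_any_weights(self, rng):
        bx = rng.uniform(0.05, 0.3, 10)
        s = make_instrument_set(bx, 0.4 * bx, rng.uniform(0.01, 0.05, 10))
        assert mr.ivw(s).beta == pytest.approx(0.4, abs=1e-12)

    def test_equals_zero_intercept_wls_slope(self, rng):
        bx = rng.uniform(0.05, 0.3, 16)
        by = 0.2 * bx + rng.normal(0, 0.02, 16)
        se = rng.uniform(0.01, 0.05, 16)
        s = make_instrument_set(bx, by, se)
        v = 1.0 / se**2
        slope = np.sum(v * bx * by) / np.sum(v * bx**2)
        assert mr.ivw(s).beta == pytest.approx(slope, abs=1e-10)

    def test_zero_exposure_beta_errors(self):
        s = make_instrument_set(np.array([0.0, 0.1, 0.2]), np.zeros(3), np.full(3, 0.01))
        with pytest.raises(ValueError, match="Wald"):
            mr.ivw(s)


class TestEgger:
    def test_fewer_than_three_instruments_error(self):
        s = make_instrument_set(np.array([0.1, 0.2]), np.array([0.0, 0.1]), np.array([0.01, 0.01]))
        with pytest.raises(ValueError, match="at least 3"):
            mr.mr_egger(s)

    def test_pleiotropy_intercept_recovery(self):
        """Constant directional pleiotropy lands in the intercept and the
        slope still recovers the causal effect."""
        cover_slope, cover_int = 0, 0
        for rep in range(40):
            rng = np.random.default_rng(300 + rep)
            m = 16
            bx = rng.uniform(0.05, 0.3, m)
            se = rng.uniform(0.01, 0.03, m)
            delta = 0.02
            by = delta + 0.2 * bx + rng.normal(0, se)
            res = mr.mr_egger(make_instrument_set(bx, by, se))
            t = stats.t.ppf(0.975, m - 2)
            cover_slope += abs(res.beta - 0.2) <= t * res.se
            cover_int += abs(res.egger_intercept - delta) <= t * res.egger_intercept_se
        assert cover_slope >= 32
        assert cover_int >= 32

    def test_forcing_zero_intercept_reproduces_ivw(self, rng):
        bx = rng.uniform(0.05, 0.3, 12)
        by = 0.15 * bx + rng.normal(0, 0.02, 12)
        se = rng.uniform(0.01, 0.05, 12)
        s = make_instrument_set(bx, by, se)
        v = 1.0 / se**2
        zero_int_slope = np.sum(v * bx * by) / np.sum(v * bx**2)
        assert mr.ivw(s).beta == pytest.approx(zero_int_slope, abs=1e-12)
        # and the free-intercept Egger slope differs unless the intercept ~ 0
        res = mr.mr_egger(s)
        assert abs(res.egger_intercept) < 0.05


class TestKsAndFunnel:
    def test_uniform_grid_closed_form(self):
        n = 16
        grid = (np.arange(1, n + 1) - 0.5) / n
        D, _ = mr.ks_uniformity(grid)
        assert D == pytest.approx(0.5 / n)

    def test_enriched_small_p(self):
        D, p = mr.ks_uniformity(np.full(16, 0.001))
        assert D == pytest.approx(0.999)
        assert p < 1e-10

    def test_calibration_at_n16(self):
        rng = np.random.default_rng(42)
        rejections = sum(
            mr.ks_uniformity(rng.uniform(size=16))[1] < 0.05 for _ in range(1000)
        )
        assert 30 <= rejections <= 75  # ~5% of 1000

    def test_funnel_strength(self):
        s = make_instrument_set(
            np.array([1.0, 0.5]), np.array([0.2, 0.1]), np.array([0.05, 0.05]),
            maf=np.array([0.5, 0.01]),
        )
        out = mr.funnel_data(s)
        assert out.loc[0, "strength"] == pytest.approx(np.sqrt(0.5))
        assert out.loc[1, "strength"] < 0.1  # strength -> 0 with maf -> 0
        assert out.loc[0, "wald_ratio"] == pytest.approx(0.2)


class TestPower:
    def test_discussion_arithmetic(self):
        n = mr.mr_power_n(0.05, 0.1, alpha=0.05, power=0.8)
        assert n >= 15_000
        assert n == pytest.approx(15_700, abs=100)

    def test_effect_homogeneity(self):
        n1 = mr.mr_power_n(0.05, 0.1)
        n2 = mr.mr_power_n(0.05, 0.2)
        assert n1 / n2 == pytest.approx(4.0, abs=0.01)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            mr.mr_power_n(0.0, 0.1)
        with pytest.raises(ValueError):
            mr.mr_power_n(0.05, 0.1, power=1.5)
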