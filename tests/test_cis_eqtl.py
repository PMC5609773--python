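"""Cis-window construction, additive scan, permutation null, Gumbel
calibration and stepwise conditional selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from triplemr import cis_eqtl as ce
from triplemr import synthetic as syn
from triplemr.expression_assoc import logcpm
from triplemr.io import ExpressionData
from conftest import make_ed, make_gm


def normalized(ed):
    lc = logcpm(ed.counts)
    return ExpressionData(ed.counts, ed.genes, ed.sample_ids, logcpm=lc)


def gaussian_expression(genes_by_samples, sample_ids=None):
    """Wrap a real-valued matrix as already-normalized expression."""
    g, n = genes_by_samples.shape
    ed = make_ed(np.zeros((g, n), dtype=int), sample_ids=sample_ids)
    return ExpressionData(
        ed.counts, ed.genes, ed.sample_ids, logcpm=np.asarray(genes_by_samples, float)
    )


class TestCisPairs:
    def test_window_boundary_inclusive(self):
        genes = pd.DataFrame(
            {"id": ["g"], "chrom": ["1"], "start": [500_000], "end": [510_000]}
        )
        variants = pd.DataFrame(
            {
                "id": ["in_edge", "out_edge", "in_body", "other_chrom"],
                "chrom": ["1", "1", "1", "2"],
                "pos": [760_000, 760_001, 505_000, 505_000],
                "ref": "A",
                "alt": "G",
            }
        )
        pairs = ce.cis_pairs(genes, variants, window=250_000)
        assert sorted(pairs["snp_id"]) == ["in_body", "in_edge"]

    def test_matches_bruteforce(self, rng):
        genes = pd.DataFrame(
            {
                "id": [f"g{i}" for i in range(8)],
                "chrom": rng.choice(["1", "2"], 8),
                "start": rng.integers(1, 2_000_000, 8),
            }
        )
        genes["end"] = genes["start"] + rng.integers(1000, 50_000, 8)
        variants = pd.DataFrame(
            {
                "id": [f"v{j}" for j in range(200)],
                "chrom": rng.choice(["1", "2"], 200),
                "pos": rng.integers(1, 2_500_000, 200),
                "ref": "A",
                "alt": "G",
            }
        )
        got = set(map(tuple, ce.cis_pairs(genes, variants, 250_000).values))
        expected = {
            (g["id"], v["id"])
            for _, g in genes.iterrows()
            for _, v in variants.iterrows()
            if g["chrom"] == v["chrom"]
            and g["start"] - 250_000 <= v["pos"] <= g["end"] + 250_000
        }
        assert got == expected


class TestScan:
    def test_recovers_injected_effect(self, rng):
        n = 400
        g = rng.choice([0.0, 1.0, 2.0], n, p=[0.49, 0.42, 0.09])
        y = 0.4 * g + rng.standard_normal(n)
        ed = gaussian_expression(y[None, :])
        gm = make_gm(g[:, None], sample_ids=ed.sample_ids)
        pairs = pd.DataFrame({"gene_id": ["g0"], "snp_id": ["v0"]})
        out = ce.eqtl_scan(pairs, ed, gm, rng.standard_normal((n, 2)))
        assert abs(out.loc[0, "beta"] - 0.4) < 2.5 * 0.08
        assert out.loc[0, "n_used"] == n

    def test_missing_dosages_dropped_pairwise(self, rng):
        n = 200
        g = rng.choice([0.0, 1.0, 2.0], n)
        g[:20] = np.nan
        ed = gaussian_expression(rng.standard_normal((1, n)))
        gm = make_gm(g[:, None], sample_ids=ed.sample_ids)
        pairs = pd.DataFrame({"gene_id": ["g0"], "snp_id": ["v0"]})
        out = ce.eqtl_scan(pairs, ed, gm, np.zeros((n, 0)))
        assert out.loc[0, "n_used"] == 180

    def test_monomorphic_snp_skipped(self, rng):
        n = 100
        ed = gaussian_expression(rng.standard_normal((1, n)))
        gm = make_gm(np.ones((n, 1)), sample_ids=ed.sample_ids)
        pairs = pd.DataFrame({"gene_id": ["g0"], "snp_id": ["v0"]})
        out = ce.eqtl_scan(pairs, ed, gm, np.zeros((n, 0)))
        assert len(out) == 0
        assert out.attrs["skipped"][0][2] == "monomorphic"

    def test_null_p_uniform(self, rng):
        """With genotype independent of expression, nominal p-values are
        uniform across many pairs."""
        n, m = 150, 300
        gm = make_gm(rng.choice([0.0, 1.0, 2.0], size=(n, m), p=[0.5, 0.3, 0.2]))
        ed = gaussian_expression(rng.standard_normal((m, n)))
        pairs = pd.DataFrame({"gene_id": [f"g{i}" for i in range(m)], "snp_id": [f"v{i}" for i in range(m)]})
        out = ce.eqtl_scan(pairs, ed, gm, rng.standard_normal((n, 3)))
        assert stats.kstest(out["p_nominal"], "uniform").pvalue > 0.01


class TestPermutationNull:
    def _setup(self, rng, n=200, m=1, eff=0.0, ld_rho=0.0):
        gm = syn.simulate_genotypes(n, m, maf_range=(0.2, 0.5), ld_rho=ld_rho,
                                    ld_block_size=m, seed=int(rng.integers(2**31)))
        y = rng.standard_normal(n) + eff * np.nan_to_num(gm.dosages[:, 0])
        ed = gaussian_expression(y[None, :], sample_ids=gm.sample_ids)
        return gm, ed

    def test_single_snp_min_p_uniform(self, rng):
        gm, ed = self._setup(rng)
        minp = ce.permutation_null(
            "g0", ["snp_1_0"], ed, gm, np.zeros((200, 0)), n_perm=800, seed=1
        )
        assert stats.kstest(minp, "uniform").pvalue > 0.01

    def test_order_statistic_mean_many_snps(self, rng):
        """Minimum of 50 independent uniform p-values has mean 1/51."""
        gm, ed = self._setup(rng, m=50)
        minp = ce.permutation_null(
            "g0", list(gm.variants["id"]), ed, gm, np.zeros((200, 0)),
            n_perm=1500, seed=2,
        )
        se = np.sqrt(50 / (51**2 * 52) / 1500)
        assert abs(minp.mean() - 1 / 51) < 4 * se

    def test_deterministic_under_seed(self, rng):
        gm, ed = self._setup(rng, m=5)
        kw = dict(n_perm=200, seed=7)
        a = ce.permutation_null("g0", list(gm.variants["id"]), ed, gm, np.zeros((200, 0)), **kw)
        b = ce.permutation_null("g0", list(gm.variants["id"]), ed, gm, np.zeros((200, 0)), **kw)
        np.testing.assert_array_equal(a, b)


class TestGumbel:
    def test_parameter_recovery(self, rng):
        x = stats.gumbel_r.rvs(loc=1.0, scale=0.3, size=100_000, random_state=rng)
        fit = ce.gumbel_fit(10.0 ** (-x))
        assert fit.mu == pytest.approx(1.0, abs=0.01)
        assert fit.beta_scale == pytest.approx(0.3, rel=0.01)

    def test_location_equivariance(self, rng):
        x = stats.gumbel_r.rvs(loc=2.0, scale=0.4, size=20_000, random_state=rng)
        a = ce.gumbel_fit(10.0 ** (-x))
        b = ce.gumbel_fit(10.0 ** (-(x + 1.0)))
        assert b.mu - a.mu == pytest.approx(1.0, abs=0.02)
        assert b.beta_scale == pytest.approx(a.beta_scale, rel=1e-6)

    def test_degenerate_input_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            ce.gumbel_fit(np.full(100, 0.5))

    def test_p_perm_median_and_monotonicity(self):
        fit = ce.GumbelFit(mu=2.0, beta_scale=0.5, n_perm=1000, ks_gof=0.0)
        x_med = 2.0 - 0.5 * np.log(np.log(2))
        assert ce.p_perm(fit, 10.0**-x_med) == pytest.approx(0.5)
        grid = ce.p_perm(fit, np.logspace(-10, -0.01, 40))
        assert (np.diff(grid) > 0).all()  # smaller -log10 p -> larger p_perm
        assert grid[0] < 1e-6 and grid[-1] > 0.9
        with pytest.raises(ValueError):
            ce.p_perm(fit, 0.0)

    def test_calibrated_p_tracks_empirical_p(self, rng):
        """Gumbel-calibrated gene-level p agrees with the direct empirical
        permutation p within a factor of two (single gene; the wide sweep
        lives in the acceptance suite)."""
        n = 300
        gm = syn.simulate_genotypes(n, 20, maf_range=(0.2, 0.5), seed=31)
        y = rng.standard_normal(n) + 0.12 * gm.dosages[:, 3]
        ed = gaussian_expression(y[None, :], sample_ids=gm.sample_ids)
        cov = np.zeros((n, 0))
        minp = ce.permutation_null("g0", list(gm.variants["id"]), ed, gm, cov, n_perm=1000, seed=32)
        pairs = pd.DataFrame({"gene_id": "g0", "snp_id": gm.variants["id"]})
        scan = ce.eqtl_scan(pairs, ed, gm, cov)
        p_obs = scan["p_nominal"].min()
        p_emp = (1 + (minp <= p_obs).sum()) / (len(minp) + 1)
        p_cal = ce.p_perm(ce.gumbel_fit(minp), p_obs)
        assert 0.001 <= p_emp <= 0.5
        assert 0.5 < p_cal / p_emp < 2.0


class TestBonferroniAndStepwise:
    def test_gene_bonferroni_strict(self):
        hits = pd.DataFrame({"p_perm": [0.05 / 1614, 0.05 / 1614 - 1e-9]})
        out = ce.gene_bonferroni(hits, n_genes=1614)
        assert out["significant"].tolist() == [False, True]

    def test_perfect_ld_selects_one(self, rng):
        n = 300
        g = rng.choice([0.0, 1.0, 2.0], n, p=[0.4, 0.4, 0.2])
        y = 0.5 * g + rng.standard_normal(n)
        ed = gaussian_expression(y[None, :])
        gm = make_gm(np.column_stack([g, g]), sample_ids=ed.sample_ids)
        sel = ce.stepwise_independent("g0", ["v0", "v1"], ed, gm, np.zeros((n, 0)), p_enter=0.05)
        assert len(sel) == 1

    def test_two_independent_signals_both_selected(self, rng):
        n = 500
        g1 = rng.choice([0.0, 1.0, 2.0], n, p=[0.4, 0.4, 0.2])
        g2 = rng.choice([0.0, 1.0, 2.0], n, p=[0.4, 0.4, 0.2])
        y = 0.5 * g1 + 0.5 * g2 + rng.standard_normal(n)
        ed = gaussian_expression(y[None, :])
        gm = make_gm(np.column_stack([g1, g2]), sample_ids=ed.sample_ids)
        sel = ce.stepwise_independent("g0", ["v0", "v1"], ed, gm, np.zeros((n, 0)), p_enter=0.05)
        assert sorted(sel) == ["v0", "v1"]

    def test_ld_proxy_not_selected(self):
        """One causal SNP plus a pure-LD proxy: the stepwise procedure
        keeps a single signal in most replicates."""
        kept_one = 0
        for rep in range(20):
            rng = np.random.default_rng(600 + rep)
            gm = syn.simulate_genotypes(
                500, 2, maf_range=(0.3, 0.4), ld_block_size=2, ld_rho=0.9,
                seed=700 + rep,
            )
            y = 0.5 * gm.dosages[:, 0] + rng.standard_normal(500)
            ed = gaussian_expression(y[None, :], sample_ids=gm.sample_ids)
            sel = ce.stepwise_independent(
                "g0", ["snp_1_0", "snp_1_1"], ed, gm, np.zeros((500, 0)), p_enter=0.05
            )
            kept_one += len(sel) == 1
        assert kept_one >= 18
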