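"""Outlier screening, REML variance decomposition, heritability, BLUEs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shuttlegp.phenotypes import (TrialBlues, VarianceComponents,
                                  VarianceDecomposition, descriptive_stats,
                                  flag_outliers, harmonic_means, heritability,
                                  tukey_hinges)
from shuttlegp.reml import em_reml, indicator


def _records(values, **overrides):
    n = len(values)
    base = dict(family=[f"F{i}" for i in range(n)], location="SRO", year=2020,
                generation=4, rep=1, block=1, trait="T", value=values)
    base.update(overrides)
    return pd.DataFrame(base)


class TestOutliers:
    def test_tukey_fence_example(self):
        rec = _records([1, 2, 3, 4, 100])
        flags = flag_outliers(rec)
        assert flags.tolist() == [False, False, False, False, True]
        q1, q3 = tukey_hinges(np.array([1, 2, 3, 4, 100]))
        assert (q1, q3) == (2.0, 4.0)

    def test_constant_and_symmetric_not_flagged(self):
        assert not flag_outliers(_records([5.0] * 8)).any()
        assert not flag_outliers(_records([1, 2, 3, 4, 5, 6])).any()

    def test_small_group_warns(self):
        with pytest.warns(UserWarning):
            flags = flag_outliers(_records([1, 2, 100]))
        assert not flags.any()


class TestHarmonicMeans:
    def test_balanced_design(self):
        rows = []
        for f in range(5):
            for loc in ("PAL", "SRO"):
                for rep in (1, 2, 3):
                    rows.append((f"F{f}", loc, 2020, 4, rep, 1, "T", 0.0))
        rec = pd.DataFrame(rows, columns=["family", "location", "year",
                                          "generation", "rep", "block",
                                          "trait", "value"])
        ne, nr = harmonic_means(rec)
        assert ne == pytest.approx(2.0)
        assert nr == pytest.approx(6.0)

    def test_unbalanced_locations(self):
        rows = [("F1", "PAL", 2020, 4, 1, 1, "T", 0.0),
                ("F2", "PAL", 2020, 4, 1, 1, "T", 0.0),
                ("F2", "SRO", 2020, 4, 1, 1, "T", 0.0)]
        rec = pd.DataFrame(rows, columns=["family", "location", "year",
                                          "generation", "rep", "block",
                                          "trait", "value"])
        ne, _ = harmonic_means(rec)
        assert ne == pytest.approx(2 / (1 / 1 + 1 / 2))

    def test_single_family(self):
        ne, nr = harmonic_means(_records([1.0]))
        assert (ne, nr) == (1.0, 1.0)


class TestHeritability:
    # printed variance proportions reproduce the published H2 values
    @pytest.mark.parametrize("s2g,s2gl,s2e,ne,nr,expected", [
        (24.7, 36.1, 33.0, 2, 6, 0.51),   # flowering, both locations
        (67.2, None, 28.8, 1, 3, 0.87),   # flowering within target site
        (48.8, None, 35.3, 1, 3, 0.81),   # zinc within surrogate site
        (41.3, None, 53.6, 1, 3, 0.70),   # height within target site
    ])
    def test_published_arithmetic(self, s2g, s2gl, s2e, ne, nr, expected):
        # agreement to the printed rounding precision of the source table
        assert heritability((s2g, s2gl, s2e), ne, nr) == pytest.approx(
            expected, abs=0.005 + 1e-9)

    def test_degenerate_cases(self):
        assert heritability((10.0, 0.0, 0.0), 2, 6) == 1.0
        with pytest.raises(ValueError):
            heritability((0.0, 0.0, 0.0), 2, 6)
        with pytest.raises(ValueError):
            heritability((1.0, 1.0, 1.0), 0, 6)

    @given(st.floats(0.1, 50), st.floats(0, 50), st.floats(0.1, 50),
           st.floats(0.1, 20))
    @settings(max_examples=50, deadline=None)
    def test_bounds_and_monotonicity(self, s2g, s2gl, s2e, nr):
        h = heritability((s2g, s2gl, s2e), 2, nr)
        assert 0 <= h <= 1
        assert heritability((s2g * 2, s2gl, s2e), 2, nr) >= h
        assert heritability((s2g, s2gl, s2e), 2, nr * 2) >= h


class TestReml:
    def test_balanced_oneway_matches_anova(self):
        # balanced family x rep design: REML == ANOVA method of moments
        rng = np.random.default_rng(0)
        nfam, nrep = 30, 4
        g = rng.normal(0, 2, nfam)
        y, fam = [], []
        for i in range(nfam):
            for _ in range(nrep):
                y.append(g[i] + rng.normal(0, 1))
                fam.append(f"F{i}")
        y = np.array(y)
        Z, _ = indicator(fam)
        fit = em_reml(y, np.ones((len(y), 1)), {"g": Z}, tol=1e-14, max_iter=2000)
        means = Z.T @ y / nrep
        mse = np.sum((y - Z @ means) ** 2) / (nfam * (nrep - 1))
        msb = nrep * np.sum((means - y.mean()) ** 2) / (nfam - 1)
        assert fit.sigma2_e == pytest.approx(mse, abs=1e-6)
        assert fit.sigma2["g"] == pytest.approx((msb - mse) / nrep, abs=1e-6)

    def test_zero_signal_hits_boundary(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, 200)
        Z, _ = indicator([f"F{i % 40}" for i in range(200)])
        fit = em_reml(y, np.ones((200, 1)), {"g": Z})
        assert fit.sigma2["g"] < 0.05

    def test_variance_decomposition_interface(self, small_bundle):
        rec = small_bundle.records
        vc = VarianceDecomposition(rec[rec.population == "B"], "HI").fit()
        assert isinstance(vc, VarianceComponents)
        assert vc.converged
        assert sum(vc.proportions.values()) == pytest.approx(100.0, abs=0.01)
        assert all(v >= 0 for v in [vc.sigma2_g, vc.sigma2_gxloc,
                                    vc.sigma2_block, vc.sigma2_e])
        assert 0 <= vc.heritability() <= 1
        # single-location variant drops the interaction term
        vc_sro = VarianceDecomposition(rec[rec.population == "B"], "HI",
                                       single_location="SRO").fit()
        assert vc_sro.sigma2_gxloc is None
        assert vc_sro.heritability() >= vc.heritability()


class TestBlues:
    def test_single_rep_no_blocks_returns_raw_values(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(10, 2, 12)
        rec = _records(vals, block=[b % 4 + 1 for b in range(12)])
        bt = TrialBlues(rec, "T").fit()
        merged = bt.table.merge(rec, on="family")
        np.testing.assert_allclose(merged.blue, merged.value, atol=1e-6)

    def test_vanishing_block_variance_matches_ols_means(self):
        # no block effects simulated -> GLS BLUEs equal OLS adjusted means
        rng = np.random.default_rng(3)
        nfam, nrep = 25, 3
        g = rng.normal(0, 3, nfam)
        rep_eff = [0.0, 1.5, -0.7]
        rows = []
        for r in range(nrep):
            for i in range(nfam):
                rows.append((f"F{i:02d}", "SRO", 2020, 4, r + 1, i % 8 + 1, "T",
                             g[i] + rep_eff[r] + rng.normal(0, 0.5)))
        rec = pd.DataFrame(rows, columns=["family", "location", "year",
                                          "generation", "rep", "block",
                                          "trait", "value"])
        bt = TrialBlues(rec, "T").fit()
        import statsmodels.formula.api as smf

        ols = smf.ols("value ~ C(family) + C(rep)", data=rec).fit()
        pred = rec.assign(rep=2).groupby("family").first().reset_index()
        # OLS genotype means at a common rep level, re-centred like the BLUEs
        lsmeans = []
        for f in sorted(rec.family.unique()):
            base = ols.params["Intercept"] + np.mean(
                [0] + [ols.params[f"C(rep)[T.{r}]"] for r in (2, 3)])
            extra = ols.params.get(f"C(family)[T.{f}]", 0.0)
            lsmeans.append(base + extra)
        lsmeans = np.array(lsmeans)
        lsmeans += rec.value.mean() - lsmeans.mean()
        np.testing.assert_allclose(bt.table.blue.to_numpy(), lsmeans, atol=1e-4)

    def test_blues_beat_raw_means_when_blocks_matter(self):
        # adjusting for noisy blocks improves correlation with truth
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            nfam = 40
            g = rng.normal(0, 1, nfam)
            rows = []
            for r in range(1, 4):
                order = rng.permutation(nfam)
                bl = rng.normal(0, 2.0, 8)
                for j, i in enumerate(order):
                    b = j % 8
                    rows.append((f"F{i:02d}", "SRO", 2020, 4, r, b + 1, "T",
                                 g[i] + bl[b] + rng.normal(0, 0.3)))
            rec = pd.DataFrame(rows, columns=["family", "location", "year",
                                              "generation", "rep", "block",
                                              "trait", "value"])
            blues = TrialBlues(rec, "T").fit().series().sort_index()
            raw = rec.groupby("family").value.mean().sort_index()
            truth = pd.Series(g, index=[f"F{i:02d}" for i in range(nfam)]).sort_index()
            if truth.corr(blues) > truth.corr(raw):
                wins += 1
        assert wins > n_seeds / 2

    def test_mean_equals_trial_mean(self, small_bundle):
        rec = small_bundle.records
        trial = rec[(rec.population == "B") & (rec.location == "SRO")]
        bt = TrialBlues(trial, "HI").fit()
        assert bt.table.blue.mean() == pytest.approx(
            trial[trial.trait == "HI"].value.mean())
        assert (bt.table.se > 0).all()


class TestDescriptiveStats:
    def test_cv_and_correlation(self):
        rows = []
        rng = np.random.default_rng(4)
        vals = rng.normal(50, 5, 30)
        for loc in ("PAL", "SRO"):
            for i, v in enumerate(vals):
                rows.append((f"F{i}", loc, 2020, 4, 1, 1, "T", v))
        rec = pd.DataFrame(rows, columns=["family", "location", "year",
                                          "generation", "rep", "block",
                                          "trait", "value"])
        out = descriptive_stats(rec)
        row = out[out.location == "PAL"].iloc[0]
        assert row.cv_pct == pytest.approx(100 * vals.std(ddof=1) / vals.mean())
        # identical data in both locations -> correlation exactly 1
        assert out.corr_between_locations.iloc[0] == pytest.approx(1.0)

    def test_zero_mean_cv_missing(self):
        rec = _records([-1.0, 1.0, -2.0, 2.0])
        out = descriptive_stats(rec)
        assert np.isnan(out.cv_pct.iloc[0])
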