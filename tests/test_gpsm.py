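"""Mixed-model selection mapping: REML, GLS scan, thresholds, Q-Q."""

import numpy as np
import pytest
from scipy import stats

from bovpop.gpsm import (
    VarianceComponents,
    bonferroni_threshold,
    mlma_scan,
    qq_data,
    reml_null,
)
from bovpop.popgen_stats import GRM, grm_vanraden
from bovpop.simdata import SimConfig, simulate_dataset
from tests.conftest import make_dataset


def reml_loglik_direct(sigma2_g, sigma2_e, G, y):
    """Direct-inversion restricted log-likelihood (intercept-only model)."""
    n = len(y)
    V = sigma2_g * G + sigma2_e * np.eye(n)
    Vi = np.linalg.inv(V)
    X = np.ones((n, 1))
    XViX = X.T @ Vi @ X
    beta = np.linalg.solve(XViX, X.T @ Vi @ y)
    r = y - X @ beta
    _, logdetV = np.linalg.slogdet(V)
    _, logdetX = np.linalg.slogdet(XViX)
    return float(
        -0.5 * (logdetV + logdetX + r.T @ Vi @ r + (n - 1) * np.log(2 * np.pi))
    )


class TestREML:
    def _sim(self, seed, pve, n=120, m=600):
        cfg = SimConfig(seed=seed, n_populations=1, n_per_population=n,
                        n_markers=m, founder_pool_size=200, polygenic_pve=pve)
        ds, _ = simulate_dataset(cfg)
        y = ds.samples.birth_year.to_numpy(dtype=float)
        return ds, y, grm_vanraden(ds)

    def test_eigendecomposition_matches_direct_inversion_oracle(self):
        rng = np.random.default_rng(2)
        n = 50
        Z = rng.integers(0, 3, size=(n, 120)).astype(np.uint8)
        ds = make_dataset(Z)
        g = grm_vanraden(ds)
        y = rng.normal(size=n) + 0.5 * g.values @ rng.normal(size=n)
        vc = reml_null(y, g)
        ll_direct = reml_loglik_direct(max(vc.sigma2_g, 1e-12), vc.sigma2_e, g.values, y - y.mean())
        assert vc.log_likelihood == pytest.approx(ll_direct, abs=1e-6)
        # the REML optimum cannot be beaten by nearby ratios
        for factor in (0.5, 2.0):
            ll_alt = reml_loglik_direct(
                max(vc.sigma2_g, 1e-12) * factor, vc.sigma2_e, g.values, y - y.mean()
            )
            assert ll_alt <= vc.log_likelihood + 1e-6

    def test_pure_noise_gives_small_pve_on_average(self):
        # single-replicate REML on a near-identity GRM is noisy; the
        # average over independent phenotype draws must sit near zero
        ds, _, g = self._sim(5, 0.0, n=200, m=400)
        rng = np.random.default_rng(0)
        pves = [reml_null(rng.normal(size=200), g).pve for _ in range(8)]
        assert np.mean(pves) < 0.15

    def test_constant_y_rejected(self):
        ds, _, g = self._sim(6, 0.0, n=60, m=200)
        with pytest.raises(ValueError, match="constant"):
            reml_null(np.full(60, 2000.0), g)

    def test_too_few_individuals_rejected(self):
        g = GRM(values=np.eye(10), allele_freqs=np.full(5, 0.5), n_markers=5)
        with pytest.raises(ValueError, match="30"):
            reml_null(np.arange(10.0), g)


class TestScan:
    def test_reduces_to_ols_when_genomic_variance_zero(self):
        rng = np.random.default_rng(7)
        calls = rng.binomial(2, 0.4, size=(80, 30)).astype(np.uint8)
        ds = make_dataset(calls)
        y = rng.normal(size=80)
        g = grm_vanraden(ds)
        vc = VarianceComponents(0.0, 1.0, 0.0, 0.0, 0)
        res = mlma_scan(ds, y, vc, g)
        for j in range(30):
            x = calls[:, j].astype(float)
            if x.std() == 0:
                continue
            slope, _, rval, p_ols, _ = stats.linregress(x, y)
            row = res.table.iloc[j]
            assert row["effect"] == pytest.approx(slope, rel=1e-9)
            assert row["p_value"] == pytest.approx(p_ols, rel=1e-6)

    def test_pvalues_invariant_to_marker_order_and_sign_flips(self):
        rng = np.random.default_rng(8)
        calls = rng.binomial(2, 0.5, size=(100, 40)).astype(np.uint8)
        ds = make_dataset(calls)
        y = rng.normal(size=100)
        g = grm_vanraden(ds)
        vc = reml_null(y, g)
        base = mlma_scan(ds, y, vc, g).table.set_index("marker_id")
        perm = rng.permutation(40)
        shuffled = mlma_scan(ds.take_markers(perm), y, vc, g).table.set_index("marker_id")
        np.testing.assert_allclose(
            base.loc[shuffled.index, "p_value"], shuffled["p_value"], rtol=1e-9
        )
        flipped_calls = (2 - calls).astype(np.uint8)
        flipped = mlma_scan(make_dataset(flipped_calls), y, vc, g).table
        np.testing.assert_allclose(flipped["effect"], -base["effect"].to_numpy(), rtol=1e-9)
        np.testing.assert_allclose(flipped["p_value"], base["p_value"].to_numpy(), rtol=1e-9)

    def test_monomorphic_marker_skipped(self):
        calls = np.hstack([
            np.zeros((50, 1), dtype=np.uint8),
            np.random.default_rng(0).binomial(2, 0.5, (50, 5)).astype(np.uint8),
        ])
        ds = make_dataset(calls)
        y = np.random.default_rng(1).normal(size=50)
        g = grm_vanraden(ds)
        res = mlma_scan(ds, y, VarianceComponents(0.0, 1.0, 0.0, 0.0, 0), g)
        assert not res.table["tested"].iloc[0]
        assert np.isnan(res.table["p_value"].iloc[0])


class TestThresholdAndQQ:
    @pytest.mark.parametrize(
        "m,expected", [(39_043, 0.05 / 39_043), (1, 0.05), (20, 2.5e-3)]
    )
    def test_bonferroni(self, m, expected):
        assert bonferroni_threshold(m) == pytest.approx(expected)
        assert bonferroni_threshold(39_043) == pytest.approx(1.2806e-6, rel=1e-4)

    def test_qq_expected_quantiles_formula(self):
        exp, obs, _ = qq_data(np.array([0.5, 0.5, 0.5]))
        np.testing.assert_allclose(exp, -np.log10([1 / 6, 3 / 6, 5 / 6]))
        np.testing.assert_allclose(obs, -np.log10([0.5, 0.5, 0.5]))

    def test_uniform_p_inflation_near_one(self, rng):
        p = rng.uniform(size=2000)
        _, _, infl = qq_data(p)
        assert 0.9 < infl < 1.1

    def test_tiny_p_dominate_expected(self):
        exp, obs, infl = qq_data(np.full(100, 1e-10))
        assert (obs > exp).all() and infl > 1

    def test_out_of_range_p_rejected_and_zero_clamped(self):
        with pytest.raises(ValueError):
            qq_data(np.array([0.5, 1.5]))
        exp, obs, _ = qq_data(np.array([0.0, 0.5]))
        assert np.isfinite(obs).all()


class TestMixedModelControlsStructure:
    def test_inflation_closer_to_one_than_plain_regression(self):
        """Under a polygenic null the mixed model should de-inflate the
        test statistics relative to ignoring relatedness."""
        wins = 0
        reps = 5
        for rep in range(reps):
            cfg = SimConfig(seed=300 + rep, n_populations=1, n_per_population=300,
                            n_markers=1000, founder_pool_size=10, polygenic_pve=0.6)
            ds, _ = simulate_dataset(cfg)
            y = ds.samples.birth_year.to_numpy(dtype=float)
            g = grm_vanraden(ds)
            vc = reml_null(y, g)
            mixed = mlma_scan(ds, y, vc, g)
            plain = mlma_scan(ds, y, VarianceComponents(0.0, 1.0, 0.0, 0.0, 0), g)
            _, _, infl_mixed = qq_data(mixed.table.loc[mixed.table.tested, "p_value"].to_numpy())
            _, _, infl_plain = qq_data(plain.table.loc[plain.table.tested, "p_value"].to_numpy())
            if abs(infl_mixed - 1) < abs(infl_plain - 1):
                wins += 1
        assert wins >= 4
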