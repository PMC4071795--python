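import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from meiomap import genmodel
from meiomap.genmodel import (ChainSettings, bonferroni, call_qtl,
                              effective_segments, fit_bayes,
                              fit_repeatability, pedigree_A, residual_weights,
                              single_snp_test)


def _markers(k, chrom="1", spacing=1000):
    return pd.DataFrame({"snp_id": [f"s{j}" for j in range(k)], "chrom": chrom,
                         "bp": (np.arange(k) + 1) * spacing,
                         "ref": "A", "alt": "B"})


class TestPedigreeA:
    def test_unrelated_founders(self):
        ped = pd.DataFrame({"offspring_id": ["a", "b"], "sire_id": ["0", "0"]})
        A, order = pedigree_A(ped, ["a", "b"])
        np.testing.assert_array_equal(A, np.eye(2))

    def test_parent_offspring_textbook_values(self):
        ped = pd.DataFrame({"offspring_id": ["p", "o"], "sire_id": ["0", "p"]})
        A, order = pedigree_A(ped, ["p", "o"])
        assert A[0, 1] == 0.5
        assert A[1, 1] == 1.0

    def test_cycle_detection(self):
        ped = pd.DataFrame({"offspring_id": ["a", "b"], "sire_id": ["b", "a"]})
        with pytest.raises(ValueError, match="cycle"):
            pedigree_A(ped, ["a", "b"])

    def test_matches_recursive_definition(self):
        rng = np.random.default_rng(8)
        ids = [f"x{i}" for i in range(20)]
        parent = {}
        rows = []
        for i, ind in enumerate(ids):
            p = ids[rng.integers(0, i)] if i > 2 and rng.random() < 0.7 else "0"
            parent[ind] = None if p == "0" else p
            rows.append((ind, p))
        ped = pd.DataFrame(rows, columns=["offspring_id", "sire_id"])
        A, order = pedigree_A(ped, ids)

        from functools import lru_cache
        idx = {s: i for i, s in enumerate(ids)}

        @lru_cache(maxsize=None)
        def a(i, j):
            if i == j:
                return 1.0  # single known parent, dam a founder: no inbreeding
            if idx[i] > idx[j]:
                i, j = j, i
            p = parent[j]
            return 0.5 * a(i, p) if p is not None else 0.0

        for i in ids:
            for j in ids:
                assert A[idx[i], idx[j]] == pytest.approx(a(i, j), abs=1e-12)


class TestResidualWeights:
    def test_zero_heritability_limit(self):
        assert residual_weights(0.0, 0.4, 0.3, 1) == pytest.approx(1.0)
        n = 5
        assert residual_weights(0.0, 0.4, 0.3, n) == pytest.approx(
            n / (1 + (n - 1) * 0.3))

    def test_published_parameter_values(self):
        """h2=0.26, c=0.40, t=0.33, n=1 -> (1-0.26)/(0.104+1-0.26)."""
        w = residual_weights(0.26, 0.40, 0.33, 1)
        assert w == pytest.approx(0.74 / 0.844, abs=1e-12)

    def test_large_family_limit(self):
        w = residual_weights(0.26, 0.40, 0.33, 10 ** 8)
        lim = (1 - 0.26) / (0.4 * 0.26 + 0.33 - 0.26)
        assert w == pytest.approx(lim, abs=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            residual_weights(0.5, 0.4, 0.4, 1)  # h2 > t
        with pytest.raises(ValueError):
            residual_weights(0.2, 0.4, 0.3, 0)


class TestFitRepeatability:
    def _simulate(self, h2, seed, q=120, nrec=5):
        rng = np.random.default_rng(seed)
        rows = [(f"S{i}", "0") for i in range(20)]
        rows += [(f"S{i}", f"S{int(rng.integers(0, i))}") for i in range(20, q)]
        ped = pd.DataFrame(rows, columns=["offspring_id", "sire_id"])
        sires = [f"S{i}" for i in range(q)]
        A, order = pedigree_A(ped, sires)
        from scipy import linalg
        se = 1.0
        sa = h2 * se / (1 - h2) if h2 > 0 else 0.0
        u = linalg.cholesky(A, lower=True) @ rng.standard_normal(q) * math.sqrt(sa)
        recs = [(s, u[i] + rng.standard_normal() * math.sqrt(se))
                for i, s in enumerate(order) for _ in range(nrec)]
        grn = pd.DataFrame(recs, columns=["sire_id", "grn"])
        return grn, A, order

    def test_null_recovery(self):
        grn, A, order = self._simulate(0.0, 1, q=200)
        fit = fit_repeatability(grn, A, order,
                                ChainSettings(iterations=2500, burn_in=500, seed=1))
        assert fit.h2 < 0.1

    def test_reproducible_chains(self):
        grn, A, order = self._simulate(0.3, 2)
        ch = ChainSettings(iterations=500, burn_in=100, seed=9)
        f1 = fit_repeatability(grn, A, order, ch)
        f2 = fit_repeatability(grn, A, order, ch)
        pd.testing.assert_frame_equal(f1.samples, f2.samples)

    def test_h2_bounded_by_repeatability(self):
        grn, A, order = self._simulate(0.3, 3)
        fit = fit_repeatability(grn, A, order,
                                ChainSettings(iterations=1500, burn_in=300, seed=3))
        assert 0.0 <= fit.h2 <= fit.repeatability <= 1.0

    def test_non_positive_definite_A_raises(self):
        grn = pd.DataFrame({"sire_id": ["a", "b"], "grn": [1.0, 2.0]})
        A = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            fit_repeatability(grn, A, ["a", "b"])


class TestFitBayes:
    def test_null_inclusion_matches_prior_rate(self):
        rng = np.random.default_rng(0)
        Z = rng.integers(0, 3, size=(150, 1500)).astype(float)
        y = rng.normal(size=150)
        fit = fit_bayes(y, Z, _markers(1500), method="BayesB", pi=0.995,
                        chain=ChainSettings(iterations=2500, burn_in=500, seed=1))
        assert fit.mean_included_fraction == pytest.approx(0.005, abs=0.001)

    def test_bayesc_pi0_equals_ridge(self):
        """BayesC with pi=0 and unit weights is a ridge-type shrinkage fit."""
        rng = np.random.default_rng(4)
        n, k = 100, 50
        Z = rng.integers(0, 3, size=(n, k)).astype(float)
        Zc = Z - Z.mean(axis=0)
        s_true = rng.normal(scale=0.15, size=k)
        sigma_e = 1.0
        y = Zc @ s_true + rng.normal(scale=math.sqrt(sigma_e), size=n)
        fit = fit_bayes(y, Z, _markers(k), method="BayesC", pi=0.0,
                        chain=ChainSettings(iterations=4000, burn_in=1000, seed=4))
        lam = sigma_e / 0.15 ** 2
        ridge = np.linalg.solve(Zc.T @ Zc + lam * np.eye(k), Zc.T @ (y - y.mean()))
        r = np.corrcoef(fit.effects, ridge)[0, 1]
        assert r > 0.99

    def test_planted_qtl_dominates_windows(self):
        rng = np.random.default_rng(6)
        n, k = 200, 1000
        Z = rng.integers(0, 3, size=(n, k)).astype(float)
        markers = _markers(k, spacing=200_000)  # 5 SNPs / Mb, 200 windows
        j = 500
        beta = math.sqrt(0.25 / Z[:, j].var())
        y = Z[:, j] * beta
        y = y - y.mean() + rng.normal(size=n)
        fit = fit_bayes(y, Z, markers, method="BayesB", pi=0.995,
                        chain=ChainSettings(iterations=2000, burn_in=500, seed=6))
        qwin = fit.window_index[j]
        assert int(fit.windows["pct_var"].idxmax()) == qwin
        assert fit.windows["wppa"].iloc[qwin] > fit.windows["wppa"].mean()
        report = call_qtl(fit)
        assert ((report.candidates["window"] == fit.windows["window"].iloc[qwin])
                & (report.candidates["chrom"] == fit.windows["chrom"].iloc[qwin])
                ).any()
        assert report.candidates["candidate_snp"].iloc[0] == f"s{j}"

    def test_reproducible_and_validates(self):
        rng = np.random.default_rng(1)
        Z = rng.integers(0, 3, size=(50, 100)).astype(float)
        y = rng.normal(size=50)
        ch = ChainSettings(iterations=400, burn_in=100, seed=2)
        f1 = fit_bayes(y, Z, _markers(100), pi=0.9, chain=ch)
        f2 = fit_bayes(y, Z, _markers(100), pi=0.9, chain=ch)
        np.testing.assert_array_equal(f1.ppi, f2.ppi)
        np.testing.assert_array_equal(f1.var_g, f2.var_g)
        with pytest.raises(ValueError):
            fit_bayes(y, Z, _markers(100), pi=1.0)
        with pytest.raises(ValueError):
            fit_bayes(y, Z, _markers(100), weights=np.zeros(50))

    def test_window_variances_sum_to_total_for_disjoint_snps(self):
        """With one SNP per window, window variances are exact shares of the
        per-sample genetic variance up to between-window covariance."""
        rng = np.random.default_rng(3)
        Z = rng.integers(0, 3, size=(120, 30)).astype(float)
        markers = _markers(30, spacing=1_000_000)  # one SNP per window
        y = Z[:, 5] - Z[:, 5].mean() + rng.normal(size=120)
        fit = fit_bayes(y, Z, markers, method="BayesC", pi=0.0,
                        chain=ChainSettings(iterations=1500, burn_in=500, seed=3))
        # shares are non-negative and the planted window is the largest
        assert (fit.windows["pct_var"] >= 0).all()
        assert int(fit.windows["pct_var"].idxmax()) == fit.window_index[5]


class TestQtlReport:
    def test_zero_thresholds_return_all_windows(self):
        rng = np.random.default_rng(2)
        Z = rng.integers(0, 3, size=(60, 40)).astype(float)
        y = rng.normal(size=60)
        fit = fit_bayes(y, Z, _markers(40, spacing=500_000), pi=0.9,
                        chain=ChainSettings(iterations=600, burn_in=100, seed=5))
        report = call_qtl(fit, min_pct_var=0.0, wppa_fold=0.0)
        assert len(report.candidates) == len(fit.windows)

    def test_null_data_rarely_yields_candidates(self):
        sizes = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            Z = rng.integers(0, 3, size=(80, 400)).astype(float)
            y = rng.normal(size=80)
            fit = fit_bayes(y, Z, _markers(400, spacing=100_000), pi=0.995,
                            chain=ChainSettings(iterations=800, burn_in=200,
                                                seed=seed))
            sizes.append(len(call_qtl(fit).candidates))
        # a 0.2% variance + 1.5x WPPA double threshold keeps the null report
        # nearly empty
        assert np.median(sizes) <= 2


class TestEffectiveSegments:
    def test_log_term_unity(self):
        assert effective_segments(math.e, 1.0, 1) == pytest.approx(2 * math.e)

    def test_published_inputs(self):
        me = effective_segments(545, 1.0, 30)
        assert me == pytest.approx(32700 / math.log(545), rel=1e-12)

    def test_monotone_in_ne(self):
        vals = [effective_segments(ne, 1.0, 30) for ne in np.linspace(3, 2000, 50)]
        assert np.all(np.diff(vals) > 0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            effective_segments(1.0, 1.0, 30)

    def test_bonferroni(self):
        me = effective_segments(545, 1.0, 30)
        assert bonferroni(1e-6, me)
        assert not bonferroni(0.01, me)


class TestSingleSnpTest:
    def test_reduces_to_anova_with_identity_A(self):
        rng = np.random.default_rng(7)
        n = 90
        snp = rng.integers(0, 3, size=n)
        y = rng.normal(size=n) + 0.3 * snp
        p = single_snp_test(y, snp, np.eye(n), sigma2_a=0.0, sigma2_e=1.0)
        groups = [y[snp == g] for g in np.unique(snp)]
        p_anova = stats.f_oneway(*groups).pvalue
        assert p == pytest.approx(p_anova, abs=1e-10)

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(11)
        n, reps = 60, 400
        snp = rng.integers(0, 3, size=n)
        A = np.eye(n)
        hits = 0
        for _ in range(reps):
            y = rng.normal(size=n)
            hits += single_snp_test(y, snp, A, 0.3, 1.0) < 0.05
        se = math.sqrt(0.05 * 0.95 / reps)
        assert abs(hits / reps - 0.05) < 3 * se

    def test_monomorphic_raises(self):
        with pytest.raises(ValueError):
            single_snp_test(np.zeros(10), np.ones(10), np.eye(10), 0.1, 1.0)

    def test_collinear_snp_detected(self):
        n = 40
        snp = np.repeat([0, 2], n // 2)
        y = snp.astype(float)
        p = single_snp_test(y, snp, np.eye(n), 0.0, 1e-12)
        assert p < 1e-30
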