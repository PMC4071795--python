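import numpy as np
import pandas as pd
import pytest
from scipy import stats

from meiomap.haplotypes import PhasedGenotypes
from meiomap.simdata import (SimConfig, apply_genotyping_error,
                             apply_switch_error, build_recomb_map,
                             draw_founder_haplotypes, make_gamete,
                             simulate_population, switch_from)


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(grn_h2=1.5)
    with pytest.raises(ValueError):
        SimConfig(switch_error_rate=-0.1)
    with pytest.raises(ValueError):
        SimConfig(founder_pool_size=1)
    with pytest.raises(ValueError):
        SimConfig(n_chromosomes=2, chrom_lengths_mb=(50.0,))
    with pytest.raises(ValueError):
        SimConfig(n_chromosomes=1, chrom_lengths_mb=(10.0,),
                  window_intensity={"1": [1.0] * 3})


def test_recomb_map_normalization():
    cfg = SimConfig(n_chromosomes=1, chrom_lengths_mb=(50.0,),
                    window_intensity={"1": [1.0] * 50})
    m = build_recomb_map(cfg)
    assert np.allclose(m["weight"], 0.02)

    cfg = SimConfig(n_chromosomes=1, chrom_lengths_mb=(10.0,),
                    window_intensity={"1": [10.0] + [1.0] * 9})
    m = build_recomb_map(cfg)
    assert m["weight"].iloc[0] == pytest.approx(10 / 19)
    assert np.allclose(m["weight"].iloc[1:], 1 / 19)

    cfg = SimConfig(n_chromosomes=2, chrom_lengths_mb=(30.0, 20.0),
                    n_hot_windows=5, hot_multiplier=8.0, seed=3)
    m1, m2 = build_recomb_map(cfg), build_recomb_map(cfg)
    pd.testing.assert_frame_equal(m1, m2)
    per_chrom = m1.groupby("chrom")["weight"].sum()
    assert np.allclose(per_chrom, 1.0)


class TestFounders:
    def test_zero_mutation_copies_pool_member(self):
        cfg = SimConfig(n_chromosomes=1, chrom_lengths_mb=(20.0,),
                        founder_pool_size=5, founder_mutation_rate=0.0,
                        founder_segment_mb=None, seed=1)
        haps, pool = draw_founder_haplotypes(cfg, 10)
        for h in haps["1"]:
            assert any(np.array_equal(h, p) for p in pool["1"])

    def test_full_mutation_flips_every_site(self):
        cfg = SimConfig(n_chromosomes=1, chrom_lengths_mb=(20.0,),
                        founder_pool_size=2, founder_mutation_rate=1.0,
                        founder_segment_mb=None, seed=1)
        haps, pool = draw_founder_haplotypes(cfg, 6)
        for h in haps["1"]:
            assert any(np.array_equal(h, 1 - p) for p in pool["1"])

    def test_mutation_rate_matches_binomial(self):
        cfg = SimConfig(n_chromosomes=1, chrom_lengths_mb=(650.0,),
                        snp_spacing_kb=61.0, founder_pool_size=2,
                        founder_mutation_rate=0.01, founder_segment_mb=None,
                        seed=1)
        haps, pool = draw_founder_haplotypes(cfg, 4)
        m = haps["1"].shape[1]
        assert m >= 10000
        flips = []
        for h in haps["1"]:
            best = min(int((h != p).sum()) for p in pool["1"])
            flips.append(best)
        frac = np.sum(flips) / (4 * m)
        se = np.sqrt(0.01 * 0.99 / (4 * m))
        assert abs(frac - 0.01) < 3 * se

    def test_pool_too_small(self):
        with pytest.raises(ValueError):
            SimConfig(founder_pool_size=1)


class TestMakeGamete:
    def _setup(self, length_mb=158.3):
        cfg = SimConfig(n_chromosomes=1, chrom_lengths_mb=(length_mb,), seed=5)
        rng = np.random.default_rng(5)
        bp = np.sort(rng.choice(int(length_mb * 1e6), 200, replace=False)) + 1
        parent = rng.integers(0, 2, size=(2, 200)).astype(np.int8)
        nw = int(np.ceil(length_mb))
        weights = np.full(nw, 1.0 / nw)
        return cfg, bp, parent, weights, rng

    def test_zero_length_chromosome_never_recombines(self):
        cfg = SimConfig(n_chromosomes=1, chrom_lengths_mb=(1e-9,), seed=5)
        rng = np.random.default_rng(0)
        bp = np.array([1])
        parent = np.array([[0], [1]], dtype=np.int8)
        for _ in range(20):
            gam, pos, _ = make_gamete(parent, bp, 1e-9, np.array([1.0]), cfg,
                                      1.0, rng)
            assert pos.size == 0

    def test_crossover_count_pmf(self):
        """P(t=0) for x=1.583 M under Binomial(4, x/4), 50k draws."""
        cfg, bp, parent, weights, rng = self._setup(158.3)
        n_draw = 50_000
        zeros = 0
        for _ in range(n_draw):
            _, pos, _ = make_gamete(parent, bp, 158.3, weights, cfg, 1.0, rng)
            zeros += pos.size == 0
        p0 = (1 - 1.583 / 4) ** 4
        se = np.sqrt(p0 * (1 - p0) / n_draw)
        assert abs(zeros / n_draw - p0) < 3 * se

    def test_mean_crossover_count_is_morgan_length(self):
        cfg, bp, parent, weights, rng = self._setup(158.3)
        total = sum(make_gamete(parent, bp, 158.3, weights, cfg, 1.0, rng)[1].size
                    for _ in range(50_000))
        x = 1.583
        sd = np.sqrt(4 * (x / 4) * (1 - x / 4) / 50_000)
        assert abs(total / 50_000 - x) < 3 * sd

    def test_excessive_multiplier_raises(self):
        cfg, bp, parent, weights, rng = self._setup(158.3)
        with pytest.raises(ValueError, match="max_crossovers_N"):
            make_gamete(parent, bp, 158.3, weights, cfg, 3.0, rng)


class TestErrorProcesses:
    def test_zero_rates_leave_data_unchanged(self, small_sim):
        _, data, _, _ = small_sim
        rng = np.random.default_rng(0)
        before = {c: h.copy() for c, h in data.haplotypes.items()}
        t1 = apply_genotyping_error(data, 0.0, rng)
        t2 = apply_switch_error(data, 0.0, rng)
        assert t1.empty and t2.empty
        for c in data.chromosomes:
            np.testing.assert_array_equal(before[c], data.haplotypes[c])

    def test_switch_is_involution(self):
        rng = np.random.default_rng(1)
        h = rng.integers(0, 2, size=(2, 40)).astype(np.int8)
        orig = h.copy()
        switch_from(h, 13)
        assert not np.array_equal(h, orig)
        switch_from(h, 13)
        np.testing.assert_array_equal(h, orig)

    def test_conversion_invisible_in_homozygous_region(self):
        from meiomap.simdata import apply_gene_conversion
        cfg = SimConfig(n_chromosomes=1, chrom_lengths_mb=(1.0,),
                        gene_conversion_rate=5.0, conversion_tract_kb=500.0,
                        seed=2)
        rng = np.random.default_rng(2)
        bp = np.arange(1, 101) * 10_000
        hom = np.zeros((2, 100), dtype=np.int8)  # parent homozygous everywhere
        origin = np.zeros(100, dtype=np.int64)
        gam = hom[0].copy()
        apply_gene_conversion(gam, hom, origin, bp, 1_000_000, cfg, rng)
        np.testing.assert_array_equal(gam, hom[0])

    def test_genotyping_error_changes_code(self, small_sim):
        _, data, _, _ = small_sim
        data = data.copy()
        rng = np.random.default_rng(3)
        before = {c: data.genotypes(c).copy() for c in data.chromosomes}
        tab = apply_genotyping_error(data, 0.01, rng)
        assert len(tab) > 0
        changed = sum(int((before[c] != data.genotypes(c)).sum())
                      for c in data.chromosomes)
        assert changed == len(tab)


class TestSimulatePopulation:
    def test_pedigree_size_and_determinism(self):
        cfg = SimConfig(n_chromosomes=1, chrom_lengths_mb=(30.0,), n_sires=10,
                        offspring_per_sire=3, seed=9)
        d1, p1, t1 = simulate_population(cfg)
        d2, p2, t2 = simulate_population(cfg)
        assert (p1["analysis_pair"].sum()) == 30
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(t1.true_crossovers, t2.true_crossovers)
        for c in d1.chromosomes:
            np.testing.assert_array_equal(d1.haplotypes[c], d2.haplotypes[c])

    def test_truth_positions_in_bounds(self, small_sim):
        cfg, _, _, truth = small_sim
        for chrom, length in truth.chrom_lengths_bp.items():
            sub = truth.true_crossovers[truth.true_crossovers["chrom"] == chrom]
            assert ((sub["bp"] >= 1) & (sub["bp"] <= length)).all()

    def test_crossover_counts_follow_binomial(self):
        """Chi-square GOF of per-chromosome counts vs Binomial(4, x/4)."""
        cfg = SimConfig(n_chromosomes=1, chrom_lengths_mb=(100.0,), n_sires=100,
                        offspring_per_sire=50, grn_h2=0.0, seed=21)
        _, ped, truth = simulate_population(cfg)
        gametes = ped[ped["analysis_pair"]]["offspring_id"]
        counts = truth.crossover_counts(gametes).to_numpy()
        obs = np.bincount(counts, minlength=5)[:5]
        p = stats.binom.pmf(np.arange(5), 4, 0.25)
        chi2, pval = stats.chisquare(obs, p * len(counts))
        assert pval > 0.01

    def test_hot_window_share_matches_weights(self):
        cfg = SimConfig(n_chromosomes=1, chrom_lengths_mb=(50.0,), n_sires=200,
                        offspring_per_sire=12, n_hot_windows=10,
                        hot_multiplier=10.0, grn_h2=0.0, seed=22)
        _, ped, truth = simulate_population(cfg)
        weights = truth.recomb_map.set_index("window")["weight"]
        tx = truth.true_crossovers
        assert len(tx) > 1000
        emp = ((tx["bp"] - 1) // 1_000_000).value_counts(normalize=True)
        emp = emp.reindex(weights.index, fill_value=0.0)
        l1 = float(np.abs(emp - weights).sum())
        # L1 convergence scale ~ sqrt(n_windows / n_events)
        assert l1 < 3 * np.sqrt(len(weights) / len(tx))

    def test_null_heritability_gives_binomial_sire_variance(self):
        cfg = SimConfig(n_chromosomes=2, chrom_lengths_mb=(100.0, 100.0),
                        n_sires=200, offspring_per_sire=50, grn_h2=0.0, seed=23)
        _, ped, truth = simulate_population(cfg)
        pairs = ped[ped["analysis_pair"]]
        counts = truth.crossover_counts(pairs["offspring_id"])
        df = pairs.assign(grn=counts.to_numpy())
        sire_means = df.groupby("sire_id")["grn"].mean()
        # per-chromosome Binomial(4, 1/4) variance = 0.75; two chromosomes
        expected = 2 * 4 * 0.25 * 0.75 / 50
        assert abs(sire_means.var() - expected) / expected < 0.10

    def test_yaml_roundtrip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("n_chromosomes: 2\nchrom_lengths_mb: [40.0, 30.0]\n"
                     "n_sires: 5\noffspring_per_sire: [2, 4]\nseed: 3\n")
        cfg = SimConfig.from_yaml(p)
        assert cfg.chrom_lengths_mb == (40.0, 30.0)
        assert cfg.offspring_per_sire == (2, 4)
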