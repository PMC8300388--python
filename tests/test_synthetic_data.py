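import numpy as np
import pytest

from panelgp.density_metrics import adjacent_gaps, adjacent_r2
from panelgp.synthetic_data import (SimulationConfig, fp_like, scs_like,
                                    simulate_genotypes, simulate_marker_map,
                                    simulate_trait)


class TestMarkerMap:
    def test_uniform_spacing_has_zero_gap_variance(self):
        cfg = SimulationConfig(n_markers=100, chromosome_lengths_bp=(100_000,),
                               spacing_model="uniform", seed=0)
        gaps = adjacent_gaps(simulate_marker_map(cfg))
        assert gaps.size == 99
        assert np.var(gaps) == 0

    def test_clustered_spacing_has_positive_gap_variance(self):
        cfg = SimulationConfig(n_markers=500,
                               chromosome_lengths_bp=(10_000_000,),
                               spacing_model="clustered", seed=0)
        gaps = adjacent_gaps(simulate_marker_map(cfg))
        assert np.var(gaps) > 0

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_markers=300, seed=7)
        a = simulate_marker_map(cfg)
        b = simulate_marker_map(cfg)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_chromosome_too_short_raises(self):
        cfg = SimulationConfig(n_markers=100, chromosome_lengths_bp=(50,))
        with pytest.raises(ValueError, match="too short"):
            simulate_marker_map(cfg)

    def test_marker_count_and_strict_ordering(self):
        cfg = SimulationConfig(n_markers=1000, seed=3)
        m = simulate_marker_map(cfg)
        assert len(m) == 1000
        for c in np.unique(m.chromosomes):
            pos = m.positions[m.chromosomes == c]
            assert np.all(np.diff(pos) > 0)


class TestGenotypes:
    def test_independence_limit_tiny_lambda(self):
        cfg = SimulationConfig(n_individuals=400, n_markers=1001,
                               chromosome_lengths_bp=(2_000_000,),
                               spacing_model="uniform",
                               ld_decay_lambda_bp=1.0, seed=1)
        ds = simulate_genotypes(simulate_marker_map(cfg), cfg)
        r2, _ = adjacent_r2(ds)
        assert r2.mean() < 0.05

    def test_correlation_at_one_lambda_gap(self):
        # two markers one decay length apart: haplotype allele correlation
        # targets exp(-1); Monte-Carlo check on 5000 haplotypes
        lam = 10_000.0
        cfg = SimulationConfig(n_individuals=2500, n_markers=2,
                               chromosome_lengths_bp=(20_000,),
                               spacing_model="uniform",
                               ld_decay_lambda_bp=lam,
                               maf_low=0.3, maf_high=0.5, seed=2)
        m = simulate_marker_map(cfg)
        assert m.positions[1] - m.positions[0] == lam
        ds = simulate_genotypes(m, cfg)
        # dosage correlation equals the haplotype allele correlation
        r = np.corrcoef(ds.dosages[:, 0], ds.dosages[:, 1])[0, 1]
        assert r == pytest.approx(np.exp(-1), abs=0.05)

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_individuals=50, n_markers=100, seed=11)
        m = simulate_marker_map(cfg)
        a = simulate_genotypes(m, cfg)
        b = simulate_genotypes(m, cfg)
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_allele_frequencies_within_band(self, small_cohort):
        ds, cfg = small_cohort
        freqs = ds.allele_frequencies()
        assert freqs.min() >= cfg.maf_low - 0.1
        assert freqs.max() <= cfg.maf_high + 0.1

    def test_adjacent_r2_decreases_with_gap(self):
        cfg = SimulationConfig(n_individuals=300, n_markers=3000,
                               chromosome_lengths_bp=(30_000_000,),
                               ld_decay_lambda_bp=100_000.0, seed=5)
        m = simulate_marker_map(cfg)
        ds = simulate_genotypes(m, cfg)
        gaps = adjacent_gaps(m)
        r2, skipped = adjacent_r2(ds)
        assert skipped == 0
        edges = np.quantile(gaps, [0, 0.25, 0.5, 0.75, 1.0])
        bins = np.clip(np.searchsorted(edges, gaps, side="right") - 1, 0, 3)
        means = [r2[bins == b].mean() for b in range(4)]
        assert all(b >= 500 for b in np.bincount(bins, minlength=4))
        assert all(means[i] >= means[i + 1] for i in range(3))

    def test_half_sib_families_raise_relatedness(self):
        base = dict(n_individuals=200, n_markers=500, seed=9)
        unrel = SimulationConfig(**base)
        fam = SimulationConfig(**base, n_families=10)
        from panelgp.gblup_engine import build_grm

        m = simulate_marker_map(unrel)
        g_u = build_grm(simulate_genotypes(m, unrel)).matrix
        g_f = build_grm(simulate_genotypes(m, fam)).matrix
        off_u = g_u[np.triu_indices(200, 1)]
        off_f = g_f[np.triu_indices(200, 1)]
        assert off_f.max() > off_u.max()
        assert np.quantile(off_f, 0.99) > np.quantile(off_u, 0.99)


class TestTraits:
    def test_noise_free_limit(self, small_cohort):
        ds, _ = small_cohort
        pheno, tbv = simulate_trait(ds, scs_like(1.0), seed=4)
        y = pheno.values_for(pheno.traits[0], ds.samples)
        assert np.corrcoef(y, tbv)[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_realized_heritability_near_target(self):
        cfg = SimulationConfig(n_individuals=1000, n_markers=1000, seed=6)
        ds = simulate_genotypes(simulate_marker_map(cfg), cfg)
        h2s = []
        for seed in range(20):
            arch = scs_like(0.3)
            pheno, tbv = simulate_trait(ds, arch, seed=seed)
            y = pheno.values_for(pheno.traits[0], ds.samples)
            h2s.append(np.var(tbv, ddof=1) / np.var(y, ddof=1))
        assert np.mean(h2s) == pytest.approx(0.3, abs=0.05)

    def test_major_qtl_dominates_effect_sizes(self):
        # with 2 major QTL at 10x the small-effect SD, a major QTL carries
        # the largest |effect| in ~94% of draws (order-statistic Monte Carlo)
        cfg = SimulationConfig(n_individuals=20, n_markers=600, seed=8)
        ds = simulate_genotypes(simulate_marker_map(cfg), cfg)
        arch = fp_like(0.5)
        rng_hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            effects = np.concatenate([
                rng.normal(0, arch.major_sd, arch.n_major_qtl),
                rng.normal(0, arch.moderate_sd, arch.n_moderate_qtl),
                rng.normal(0, arch.small_sd, arch.n_small_qtl),
            ])
            if np.argmax(np.abs(effects)) < arch.n_major_qtl:
                rng_hits += 1
        assert rng_hits >= 85

    def test_doubling_effects_quadruples_genetic_variance(self, small_cohort):
        ds, _ = small_cohort
        from panelgp.synthetic_data import TraitArchitecture

        _, tbv = simulate_trait(ds, scs_like(0.5), seed=12)
        arch2 = TraitArchitecture("SCS_like", n_small_qtl=300, small_sd=2.0,
                                  heritability=0.5)
        _, tbv2 = simulate_trait(ds, arch2, seed=12)
        ratio = np.var(tbv2, ddof=1) / np.var(tbv, ddof=1)
        assert ratio == pytest.approx(4.0, rel=1e-9)

    def test_full_determinism(self, small_cohort):
        ds, _ = small_cohort
        p1, t1 = simulate_trait(ds, scs_like(0.4), seed=99)
        p2, t2 = simulate_trait(ds, scs_like(0.4), seed=99)
        np.testing.assert_array_equal(t1, t2)
        assert p1.table.equals(p2.table)
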