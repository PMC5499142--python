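"""Synthetic-data generator: determinism, Mendelian and LD structure."""

import numpy as np
import pytest

from scafmap.ldanchor import composite_ld
from scafmap.simdata import (
    ConfigError,
    GenomeConfig,
    NoiseModel,
    apply_noise,
    simulate_cross,
    simulate_genome,
    simulate_population,
)


class TestGenome:
    def test_zero_repeat_fraction_gives_all_unique(self):
        cfg = GenomeConfig(
            n_chromosomes=18, scaffolds_per_chromosome=30, repeat_fraction=0.0
        )
        genome, truth = simulate_genome(cfg, 1)
        assert len(genome.scaffolds) == 540
        assert genome.scaffolds["is_unique"].all()

    def test_repeat_fraction_within_binomial_ci(self):
        cfg = GenomeConfig(
            n_chromosomes=20, scaffolds_per_chromosome=50, repeat_fraction=0.2
        )
        genome, _ = simulate_genome(cfg, 3)
        frac = 1.0 - genome.scaffolds["is_unique"].mean()
        # 4 sigma band around p = 0.2 for n = 1000 Bernoulli draws
        assert abs(frac - 0.2) < 4 * np.sqrt(0.2 * 0.8 / 1000)

    def test_scaffolds_tile_chromosomes(self):
        genome, _ = simulate_genome(GenomeConfig(n_chromosomes=2), 5)
        for chrom, sub in genome.scaffolds.groupby("chromosome_id"):
            sub = sub.sort_values("start_bp")
            assert sub["start_bp"].iloc[0] == 0
            assert (sub["end_bp"].iloc[:-1].to_numpy() == sub["start_bp"].iloc[1:].to_numpy()).all()

    def test_determinism_same_seed(self):
        a = simulate_genome(GenomeConfig(), 7)
        b = simulate_genome(GenomeConfig(), 7)
        assert a[0].scaffolds.equals(b[0].scaffolds)
        assert a[1].scaffolds.equals(b[1].scaffolds)

    def test_invalid_config_raises(self):
        with pytest.raises(ConfigError):
            simulate_genome(GenomeConfig(chromosome_length_bp=0), 1)
        with pytest.raises(ConfigError):
            simulate_genome(GenomeConfig(repeat_fraction=1.0), 1)


class TestCross:
    def test_zero_genetic_length_no_recombination(self):
        genome, truth = simulate_genome(GenomeConfig(n_chromosomes=1), 1)
        family, matrix, truth = simulate_cross(
            genome, truth, n_offspring=20, marker_density=50, cm_per_mb=0.0, seed=2
        )
        gam = family.offspring_gametes
        # every gamete is a single founder haplotype end to end
        assert (gam.min(axis=2) == gam.max(axis=2)).all()

    def test_poisson_crossover_mean(self):
        """1 Mb at 100 cM/Mb: one expected crossover per gamete (Haldane)."""
        genome, truth = simulate_genome(
            GenomeConfig(n_chromosomes=1, scaffolds_per_chromosome=5, repeat_fraction=0), 1
        )
        family, matrix, truth = simulate_cross(
            genome, truth, n_offspring=5000, marker_density=300, cm_per_mb=100.0, seed=3
        )
        gam = family.offspring_gametes  # (off, 2, markers)
        switches = (np.diff(gam, axis=2) != 0).sum(axis=2)
        mean = switches.mean()
        # dense markers make observed switches ~ crossover count
        assert abs(mean - 1.0) < 0.05

    def test_mendelian_consistency(self, small_cross):
        genome, truth, family, matrix = small_cross
        g = matrix.genotypes
        pa = family.parentA_genotypes[:, None]
        pb = family.parentB_genotypes[:, None]
        # transmitted alleles bounded by what each parent can donate
        min_g = (pa == 2).astype(int) + (pb == 2).astype(int)
        max_g = (pa > 0).astype(int) + (pb > 0).astype(int)
        assert (g >= min_g).all() and (g <= max_g).all()

    def test_marker_truth_coverage(self, small_cross):
        genome, truth, family, matrix = small_cross
        assert set(matrix.markers["marker_id"]) <= set(truth.markers["marker_id"])
        assert set(matrix.markers["scaffold_id"]) <= set(truth.scaffolds["scaffold_id"])

    def test_repeat_scaffolds_carry_no_markers(self):
        genome, truth = simulate_genome(GenomeConfig(n_chromosomes=2, repeat_fraction=0.4), 9)
        family, matrix, truth = simulate_cross(genome, truth, n_offspring=10, seed=10)
        non_unique = set(
            genome.scaffolds.loc[~genome.scaffolds["is_unique"], "scaffold_id"]
        )
        assert not (set(matrix.markers["scaffold_id"]) & non_unique)

    def test_too_few_offspring_raises(self):
        genome, truth = simulate_genome(GenomeConfig(n_chromosomes=1), 1)
        with pytest.raises(ConfigError):
            simulate_cross(genome, truth, n_offspring=1, seed=1)

    def test_zero_density_raises(self):
        genome, truth = simulate_genome(GenomeConfig(n_chromosomes=1), 1)
        with pytest.raises(ConfigError):
            simulate_cross(genome, truth, n_offspring=10, marker_density=0, seed=1)


class TestPopulation:
    def test_two_founders_generation_zero_perfect_ld(self):
        genome, truth = simulate_genome(
            GenomeConfig(n_chromosomes=1, scaffolds_per_chromosome=10, repeat_fraction=0), 1
        )
        _, matrix, truth = simulate_population(
            genome, truth, n_samples=40, founders=2, generations=0,
            marker_density=30, seed=2,
        )
        g = matrix.genotypes
        rng = np.random.default_rng(0)
        for _ in range(50):
            i, j = rng.choice(matrix.n_markers, size=2, replace=False)
            delta, r2, n = composite_ld(g[i], g[j], min_overlap=1)
            assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_ld_decays_with_distance(self):
        """Mean r^2 within 100 kb exceeds mean r^2 beyond 1 Mb (generations >= 5)."""
        cfg = GenomeConfig(
            n_chromosomes=2, chromosome_length_bp=3_000_000,
            scaffolds_per_chromosome=30, repeat_fraction=0.0,
        )
        genome, truth = simulate_genome(cfg, 4)
        _, matrix, truth = simulate_population(
            genome, truth, n_samples=80, founders=4, generations=6,
            marker_density=60, seed=5,
        )
        tm = truth.markers.set_index("marker_id")
        info = tm.loc[matrix.markers["marker_id"]]
        chrom = info["chromosome_id"].to_numpy()
        bp = info["chrom_bp"].to_numpy()
        g = matrix.genotypes
        rng = np.random.default_rng(1)
        near, far = [], []
        idx = np.arange(matrix.n_markers)
        while len(near) < 120 or len(far) < 120:
            i, j = rng.choice(idx, size=2, replace=False)
            if chrom[i] != chrom[j]:
                continue
            d = abs(bp[i] - bp[j])
            _, r2, _ = composite_ld(g[i], g[j], min_overlap=10)
            if np.isnan(r2):
                continue
            if d <= 100_000 and len(near) < 200:
                near.append(r2)
            elif d > 1_000_000 and len(far) < 200:
                far.append(r2)
        assert np.mean(near) > np.mean(far)

    def test_distant_ld_matches_permutation_floor(self):
        """After many generations, long-range r^2 sits at the drift floor.

        The floor is estimated independently by permuting sample labels of
        one marker, which destroys any genuine association.
        """
        cfg = GenomeConfig(
            n_chromosomes=2, chromosome_length_bp=2_000_000,
            scaffolds_per_chromosome=20, repeat_fraction=0.0,
        )
        genome, truth = simulate_genome(cfg, 6)
        _, matrix, truth = simulate_population(
            genome, truth, n_samples=60, founders=4, generations=50,
            pop_size=120, marker_density=40, seed=7,
        )
        tm = truth.markers.set_index("marker_id")
        info = tm.loc[matrix.markers["marker_id"]]
        chrom = info["chromosome_id"].to_numpy()
        bp = info["chrom_bp"].to_numpy()
        g = matrix.genotypes
        rng = np.random.default_rng(2)
        far, perm = [], []
        idx = np.arange(matrix.n_markers)
        tries = 0
        while len(far) < 150 and tries < 20000:
            tries += 1
            i, j = rng.choice(idx, size=2, replace=False)
            if chrom[i] == chrom[j] and abs(bp[i] - bp[j]) <= 1_000_000:
                continue
            _, r2, _ = composite_ld(g[i], g[j], min_overlap=10)
            _, r2p, _ = composite_ld(g[i], rng.permutation(g[j]), min_overlap=10)
            if not (np.isnan(r2) or np.isnan(r2p)):
                far.append(r2)
                perm.append(r2p)
        ratio = np.mean(far) / np.mean(perm)
        assert 0.5 < ratio < 3.0

    def test_sampled_markers_polymorphic(self):
        genome, truth = simulate_genome(GenomeConfig(n_chromosomes=1), 8)
        _, matrix, _ = simulate_population(
            genome, truth, n_samples=30, founders=2, generations=10, seed=9
        )
        g = matrix.genotypes
        assert (g.max(axis=1) > g.min(axis=1)).all()

    def test_bad_inputs_raise(self):
        genome, truth = simulate_genome(GenomeConfig(n_chromosomes=1), 1)
        with pytest.raises(ConfigError):
            simulate_population(genome, truth, n_samples=1, seed=1)
        with pytest.raises(ConfigError):
            simulate_population(genome, truth, founders=1, seed=1)


class TestNoise:
    def test_zero_noise_is_identity(self, small_cross):
        _, _, _, matrix = small_cross
        out = apply_noise(matrix, NoiseModel(0.0, 0.0, 0.0), 1)
        assert out.equals(matrix)

    def test_original_not_modified(self, small_cross):
        _, _, _, matrix = small_cross
        before = matrix.genotypes.copy()
        apply_noise(matrix, NoiseModel(0.2, 0.2, 0.1), 2)
        assert np.array_equal(matrix.genotypes, before)

    def test_missing_rate_nine_percent(self, small_cross):
        _, _, _, matrix = small_cross
        out = apply_noise(matrix, NoiseModel(0.0, 0.09, 0.0), 3)
        frac = out.missing_fraction_per_sample()
        assert abs(frac.mean() - 0.09) < 0.01

    def test_error_count_within_binomial_ci(self, matrix_factory, rng):
        g = rng.integers(0, 3, size=(1000, 100)).astype(np.int8)
        matrix = matrix_factory(g)
        out = apply_noise(matrix, NoiseModel(0.01, 0.0, 0.0), 4)
        altered = int((out.genotypes != matrix.genotypes).sum())
        n = 1000 * 100
        assert abs(altered - n * 0.01) < 4 * np.sqrt(n * 0.01 * 0.99)

    def test_error_quality_range(self, small_cross):
        _, _, _, matrix = small_cross
        out = apply_noise(matrix, NoiseModel(0.05, 0.0, 0.0), 5)
        changed = out.genotypes != matrix.genotypes
        assert changed.any()
        assert (out.qualities[changed] <= 20).all()

    def test_invalid_rates_raise(self, small_cross):
        _, _, _, matrix = small_cross
        with pytest.raises(ConfigError):
            apply_noise(matrix, NoiseModel(genotype_error_rate=1.5), 1)
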