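"""Gene dropping: map function, burn-in pool, Mendelian segregation, lethality."""

import numpy as np
import pytest

from lofmate.genedrop import (
    FounderPool,
    GenomeMap,
    burn_in_founders,
    drop_genotypes,
    kosambi,
    sample_offspring_locus,
)
from lofmate.pedigree import build_pedigree
from lofmate.synth import LocusPanel, generate_locus_panel


class TestKosambi:
    def test_zero_distance(self):
        assert kosambi(0.0) == 0.0

    def test_asymptote_at_half(self):
        assert kosambi(10.0) == pytest.approx(0.5, abs=1e-9)

    def test_closed_form_at_half_morgan(self):
        assert kosambi(0.5) == pytest.approx(0.5 * np.tanh(1.0))
        assert kosambi(0.5) == pytest.approx(0.38079707797788243)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            kosambi(-0.1)

    def test_map_spans_29_chromosomes(self):
        gmap = GenomeMap.random(100, seed=1)
        assert gmap.chromosome.max() <= 28
        r = gmap.adjacent_recombination()
        assert np.all((r >= 0) & (r <= 0.5))
        # cross-chromosome pairs segregate independently
        cross = np.diff(gmap.chromosome) != 0
        assert np.all(r[cross] == 0.5)


class TestBurnIn:
    def test_frequencies_pinned_to_targets(self):
        panel = generate_locus_panel("A", seed=2)
        gmap = GenomeMap.random(len(panel), seed=3)
        pool = burn_in_founders(panel, gmap, n_pop=300, n_generations=60, seed=4)
        assert np.abs(pool.allele_frequencies() - panel.frequencies).max() <= 0.01

    def test_no_lethal_homozygote_in_pool(self):
        panel = generate_locus_panel("C", seed=5)
        gmap = GenomeMap.random(len(panel), seed=6)
        pool = burn_in_founders(panel, gmap, n_pop=150, n_generations=30, seed=7)
        assert not np.any(pool.haplotypes.sum(axis=1) == 2)

    def test_deterministic_given_seed(self):
        panel = generate_locus_panel("A", seed=8)
        gmap = GenomeMap.random(len(panel), seed=9)
        a = burn_in_founders(panel, gmap, n_pop=100, n_generations=20, seed=10)
        b = burn_in_founders(panel, gmap, n_pop=100, n_generations=20, seed=10)
        assert np.array_equal(a.haplotypes, b.haplotypes)

    def test_tiny_population_rejected(self):
        panel = generate_locus_panel("A", seed=11)
        gmap = GenomeMap.random(len(panel), seed=12)
        with pytest.raises(ValueError):
            burn_in_founders(panel, gmap, n_pop=10, n_generations=5, seed=13)


def _carrier_pool(n: int, q: float = 0.1) -> FounderPool:
    """Pool of individuals all heterozygous at a single locus."""
    hap = np.zeros((n, 2, 1), dtype=np.int8)
    hap[:, 0, 0] = 1
    return FounderPool(hap, LocusPanel(np.array([q]), "A"))


class TestMendelianSampling:
    def test_fixed_parents_give_fixed_offspring(self):
        rng = np.random.default_rng(0)
        out = sample_offspring_locus(0, 0, 1000, rng)
        assert np.all(out == 0)

    def test_carrier_by_carrier_with_rejection_is_two_thirds_heterozygous(self):
        rng = np.random.default_rng(1)
        n = 100_000
        out = sample_offspring_locus(1, 1, n, rng, reject_lethal=True)
        assert not np.any(out == 2)
        p_het = np.mean(out == 1)
        se = np.sqrt((2 / 3) * (1 / 3) / n)
        assert abs(p_het - 2 / 3) <= 3 * se

    def test_carrier_by_clear_is_half_heterozygous(self):
        rng = np.random.default_rng(2)
        n = 100_000
        out = sample_offspring_locus(1, 0, n, rng)
        p_het = np.mean(out == 1)
        assert abs(p_het - 0.5) <= 3 * np.sqrt(0.25 / n)

    def test_chi_square_goodness_of_fit_conditional_ratios(self):
        from scipy.stats import chisquare

        rng = np.random.default_rng(3)
        n = 100_000
        out = sample_offspring_locus(1, 1, n, rng, reject_lethal=True)
        observed = [np.sum(out == 0), np.sum(out == 1)]
        stat, p = chisquare(observed, [n / 3, 2 * n / 3])
        assert p > 0.001

    def test_lethal_cross_impossible(self):
        rng = np.random.default_rng(4)
        with pytest.raises(RuntimeError):
            sample_offspring_locus(2, 2, 10, rng, reject_lethal=True)


class TestDropGenotypes:
    def _family(self, n_offspring: int):
        rows = [
            {"id": "S", "sire": "0", "dam": "0", "sex": "M", "role": "ancestor"},
            {"id": "D", "sire": "0", "dam": "0", "sex": "F", "role": "ancestor"},
        ]
        rows += [
            {"id": f"C{k}", "sire": "S", "dam": "D", "sex": "M", "role": "candidate"}
            for k in range(n_offspring)
        ]
        return build_pedigree(rows)

    def test_no_lethal_survivor_ever_emitted(self):
        ped = self._family(500)
        state = drop_genotypes(ped, _carrier_pool(4), seed=5)
        assert not np.any(state.genotypes == 2)

    def test_carrier_mating_offspring_ratio(self):
        ped = self._family(20_000)
        state = drop_genotypes(ped, _carrier_pool(4), seed=6)
        offspring = state.genotypes[2:, 0]  # founders S, D occupy rows 0-1
        p_het = np.mean(offspring == 1)
        se = np.sqrt((2 / 3) * (1 / 3) / len(offspring))
        assert abs(p_het - 2 / 3) <= 3 * se

    def test_rejection_depresses_candidate_allele_frequency(self):
        # survivors of carrier x carrier matings carry a at frequency 1/3,
        # below the parental 1/2 (conditional Mendelian expectation)
        ped = self._family(20_000)
        state = drop_genotypes(ped, _carrier_pool(4), seed=7)
        freq = state.genotypes[2:, 0].mean() / 2.0
        se = np.sqrt((1 / 3) * (2 / 3) / (2 * 20_000))
        assert freq < 0.5
        assert abs(freq - 1 / 3) <= 4 * se

    def test_deterministic_and_linked_mode_consistent(self):
        panel = generate_locus_panel("A", seed=14)
        gmap = GenomeMap.random(len(panel), seed=15)
        pool = burn_in_founders(panel, gmap, n_pop=100, n_generations=10, seed=16)
        ped = self._family(50)
        a = drop_genotypes(ped, pool, seed=17)
        b = drop_genotypes(ped, pool, seed=17)
        assert np.array_equal(a.genotypes, b.genotypes)
        linked = drop_genotypes(ped, pool, seed=17, linked=True, gmap=gmap)
        assert not np.any(linked.genotypes == 2)

    def test_long_format_export(self):
        ped = self._family(3)
        state = drop_genotypes(ped, _carrier_pool(4), seed=18)
        df = state.to_frame()
        assert set(df.columns) == {"id", "locus", "genotype"}
        assert set(df["genotype"]).issubset({"AA", "Aa", "aa"})
        assert len(df) == 5  # 5 animals x 1 locus
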