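"""Tests for synthetic families, encoded crossing tables, planted alignments."""

import itertools

import numpy as np
import pytest

from slocus import crossing as cr
from slocus import fixtures as fx
from slocus import io as sio


class TestEncodedTables:
    def test_table1_cells_and_totals(self):
        recs = fx.table1_fixture()
        assert all(r.n_fruit <= r.n_pollinations for r in recs)
        inc = [r for r in recs if r.predicted == cr.INCOMPATIBLE]
        semi = [r for r in recs if r.predicted == cr.SEMI_COMPATIBLE]
        fam81 = [r for r in inc if r.family == "8-1"]
        assert sum(r.n_fruit for r in fam81) == 0
        assert sum(r.n_pollinations for r in fam81) == 15
        fam254 = [r for r in inc if r.family == "25-4"]
        assert sum(r.n_fruit for r in fam254) == 20
        assert sum(r.n_pollinations for r in fam254) == 77
        assert sum(r.n_fruit for r in semi) == 64
        assert sum(r.n_pollinations for r in semi) == 64

    def test_table2_cells_and_totals(self):
        recs = fx.table2_fixture()
        inc = [r for r in recs if r.predicted == cr.INCOMPATIBLE]
        semi = [r for r in recs if r.predicted == cr.SEMI_COMPATIBLE]
        assert sum(r.n_fruit for r in inc) == 16
        assert sum(r.n_pollinations for r in inc) == 129
        assert sum(r.n_fruit for r in semi) == 56
        assert sum(r.n_pollinations for r in semi) == 60
        ambiguous = [r for r in recs if r.ambiguous_genotype]
        assert len(ambiguous) == 1
        assert ambiguous[0].n_pollinations == 23 and ambiguous[0].n_fruit == 10

    def test_genotype_predictions_consistent_where_unambiguous(self):
        for rec in fx.table1_fixture() + fx.table2_fixture():
            if not rec.ambiguous_genotype:
                assert cr.predict_cross_phenotype(rec.maternal, rec.paternal) == (
                    rec.predicted
                )

    def test_csv_round_trip_is_bit_identical(self, tmp_path):
        path1, path2 = tmp_path / "a.csv", tmp_path / "b.csv"
        recs = fx.table1_fixture()
        sio.write_cross_records(recs, path1)
        again = sio.read_cross_records(path1)
        sio.write_cross_records(again, path2)
        assert path1.read_text() == path2.read_text()


class TestGenerateFamily:
    def _spec(self, n=2000):
        return fx.FamilySpec(
            maternal=cr.Genotype(["S8a", "S8b"]),
            paternal=cr.Genotype(["S1c", "S1d"]),
            n_offspring=n,
        )

    def test_zero_offspring(self, rng):
        assert fx.generate_family(self._spec(0), rng) == []

    def test_segregation_fits_1111(self, rng):
        offspring = fx.generate_family(self._spec(4000), rng)
        classes = sorted(
            (
                cr.Genotype([m, p])
                for m in ("S8a", "S8b")
                for p in ("S1c", "S1d")
            ),
            key=str,
        )
        counts = [sum(1 for o in offspring if o == g) for g in classes]
        stat, df, p = cr.segregation_gof(counts)
        assert df == 3 and p > 0.001

    def test_marginal_transmission_is_one_half(self, rng):
        offspring = fx.generate_family(self._spec(10000), rng)
        k = sum(1 for o in offspring if "S8a" in o.haplotypes)
        from scipy.stats import binomtest

        assert binomtest(k, 10000, 0.5).pvalue > 1e-4

    def test_linked_group_transmits_as_unit(self, rng):
        spec = fx.FamilySpec(
            maternal=cr.Genotype(["S1a", "S1b"]),
            paternal=cr.Genotype(["S3ab", "S3c"]),
            linked_groups=fx.LINKED_GROUPS,
            n_offspring=200,
        )
        offspring = fx.generate_family(spec, rng)
        with_unit = [o for o in offspring if "S3ab" in o.haplotypes]
        assert 0 < len(with_unit) < 200
        # the unit label is atomic: members never appear separately
        for o in offspring:
            assert "S3a" not in o.haplotypes and "S3b" not in o.haplotypes

    def test_homozygous_parent_rejected(self):
        with pytest.raises(ValueError):
            fx.FamilySpec(
                maternal=cr.Genotype(["S8a"]),
                paternal=cr.Genotype(["S1c", "S1d"]),
            )


class TestSimulateCrossRecords:
    def _offspring(self, rng):
        return fx.generate_family(
            fx.FamilySpec(
                maternal=cr.Genotype(["S25a", "S25b"]),
                paternal=cr.Genotype(["S4a", "S4d"]),
                n_offspring=40,
            ),
            rng,
        )

    def test_no_leak_means_no_incompatible_fruit(self, rng):
        offspring = self._offspring(rng)
        design = [(i, j, 5) for i, j in itertools.permutations(range(12), 2)]
        records = fx.simulate_cross_records(
            offspring, fx.PhenotypeModel(p_fruit_semi=1.0), design, rng
        )
        for rec in records:
            if rec.predicted == cr.INCOMPATIBLE:
                assert rec.n_fruit == 0
            if rec.predicted == cr.SEMI_COMPATIBLE:
                assert rec.n_fruit == rec.n_pollinations

    def test_weak_allele_leak_rate(self, rng):
        offspring = self._offspring(rng)
        model = fx.PhenotypeModel(leak={"S25b": 0.59})
        design = [
            (i, j, 8)
            for i, j in itertools.permutations(range(len(offspring)), 2)
        ]
        records = fx.simulate_cross_records(offspring, model, design, rng)
        leaky = [
            r
            for r in records
            if r.predicted == cr.INCOMPATIBLE and "S25b" in r.maternal.haplotypes
        ]
        fruit = sum(r.n_fruit for r in leaky)
        polls = sum(r.n_pollinations for r in leaky)
        assert polls > 200
        se = np.sqrt(0.59 * 0.41 / polls)
        assert abs(fruit / polls - 0.59) < 4 * se

    def test_same_seed_reproduces_records(self):
        rng1, rng2 = np.random.default_rng(3), np.random.default_rng(3)
        offspring = self._offspring(np.random.default_rng(1))
        model = fx.PhenotypeModel(p_fruit_semi=0.9, leak={"S25b": 0.5})
        design = [(0, 1, 6), (2, 3, 6), (4, 5, 6)]
        r1 = fx.simulate_cross_records(offspring, model, design, rng1)
        r2 = fx.simulate_cross_records(offspring, model, design, rng2)
        assert [r.n_fruit for r in r1] == [r.n_fruit for r in r2]

    def test_invalid_design_reference(self, rng):
        offspring = self._offspring(rng)
        with pytest.raises(IndexError):
            fx.simulate_cross_records(
                offspring, fx.PhenotypeModel(), [(0, 999, 3)], rng
            )


class TestDiallelPigeonhole:
    def test_every_five_sib_diallel_has_incompatible_pair_exact(self):
        # exhaustive over all 4^5 assignments of 5 sibs to 4 mating types
        genotypes = [
            cr.Genotype([m, p]) for m in ("A", "B") for p in ("C", "D")
        ]
        for assignment in itertools.product(range(4), repeat=5):
            sibs = [genotypes[a] for a in assignment]
            outcomes = [
                [
                    cr.NOT_DONE
                    if i == j
                    else (
                        cr.NO_FRUIT
                        if cr.predict_cross_phenotype(sibs[i], sibs[j])
                        == cr.INCOMPATIBLE
                        else cr.FRUIT
                    )
                    for j in range(5)
                ]
                for i in range(5)
            ]
            count, _, _ = cr.diallel_incompatible_pairs(outcomes)
            assert count >= 1

    def test_simulated_families_always_yield_a_pair(self, rng):
        spec = fx.FamilySpec(
            maternal=cr.Genotype(["S8a", "S8b"]),
            paternal=cr.Genotype(["S1c", "S1d"]),
            n_offspring=5,
        )
        for _ in range(200):
            sibs = fx.generate_family(spec, rng)
            incompatible = [
                (i, j)
                for i, j in itertools.combinations(range(5), 2)
                if cr.predict_cross_phenotype(sibs[i], sibs[j]) == cr.INCOMPATIBLE
            ]
            assert incompatible


class TestPlantedDiversityAlignment:
    def test_zero_targets_give_invariant_alignment(self, rng):
        aln = fx.planted_diversity_alignment(8, 50, (10, 20), 0.0, 0.0, rng)
        assert len(set(aln)) == 1

    def test_realised_pi_tracks_target(self):
        from slocus.diversity import pairwise_pi

        target = 0.05
        vals = []
        for seed in range(30):
            aln = fx.planted_diversity_alignment(
                12, 400, (1, 400), target, target, np.random.default_rng(seed)
            )
            vals.append(pairwise_pi(aln))
        assert np.mean(vals) == pytest.approx(target, rel=0.05)
        assert max(abs(v - target) / target for v in vals) < 0.35

    def test_impossible_target_rejected(self, rng):
        with pytest.raises(ValueError):
            fx.planted_diversity_alignment(4, 100, (1, 50), 0.9, 0.0, rng)

    def test_invalid_hot_region(self, rng):
        with pytest.raises(ValueError):
            fx.planted_diversity_alignment(6, 100, (0, 50), 0.1, 0.0, rng)
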