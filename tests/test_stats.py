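import math
import random
import statistics

import pytest

from karyokit.model import Arm, Chromosome, Karyotype, RDNAFamily, RDNASite, classify_position
from karyokit.rearrange import autopolyploidize
from karyokit.stats import count_rdna, cvcl, mca, stats_table, tml, tml_by_genome
from tests.conftest import SPECIES_EXPECTED


def chrom(L, S, label="X1", sites=()):
    return Chromosome(label=label, long_arm_um=L, short_arm_um=S, sites=sites)


def karyo(arm_pairs, ploidy=1, species="sp"):
    chroms = [chrom(L, S, label=f"K{i}") for i, (L, S) in enumerate(arm_pairs, 1)]
    x = len(chroms) // ploidy
    return Karyotype(species, chroms, ploidy=ploidy, basic_number_x=x)


def random_karyotype(rng, n_min=2, n_max=24):
    n = rng.randint(n_min, n_max)
    pairs = [(rng.uniform(1.0, 8.0), rng.uniform(0.2, 8.0)) for _ in range(n)]
    return Karyotype(
        "rand", [chrom(L, S, label=f"K{i}") for i, (L, S) in enumerate(pairs)], 1, n
    )


# --- naive single-pass loop oracles, kept independent of the implementation


def mca_oracle(k):
    total = 0.0
    for c in k.chromosomes:
        L = max(c.long_arm_um, c.short_arm_um)
        S = min(c.long_arm_um, c.short_arm_um)
        total += (L - S) / (L + S)
    return total / len(k.chromosomes) * 100.0


def cvcl_oracle(k):
    lengths = [c.long_arm_um + c.short_arm_um for c in k.chromosomes]
    return statistics.stdev(lengths) / statistics.mean(lengths) * 100.0


class TestMCA:
    def test_all_metacentric_is_zero(self):
        assert mca(karyo([(2.0, 2.0)] * 6)) == 0.0

    def test_hand_computed_mean(self):
        # (3,1) -> 50, (1,1) -> 0; mean 25
        assert mca(karyo([(3.0, 1.0), (1.0, 1.0)])) == pytest.approx(25.0)

    def test_single_chromosome(self):
        assert mca(karyo([(7.0, 1.0)])) == pytest.approx(75.0)

    def test_set_total_variant(self):
        # sum L = 4, sum S = 2 -> (4-2)/(4+2) x 100
        k = karyo([(3.0, 1.0), (1.0, 1.0)])
        assert mca(k, set_total=True) == pytest.approx(100.0 / 3.0)


class TestCVCL:
    def test_equal_lengths_zero(self):
        assert cvcl(karyo([(2.0, 1.0)] * 5)) == 0.0

    def test_hand_computed_sample_sd(self):
        # lengths {4, 6}: sample sd = sqrt(2), mean 5 -> 28.284271 %
        assert cvcl(karyo([(3.0, 1.0), (4.0, 2.0)])) == pytest.approx(28.284271, abs=1e-6)

    def test_hand_computed_three_lengths(self):
        # lengths {1, 2, 3}: sample sd = 1, mean 2 -> 50 %
        assert cvcl(karyo([(0.6, 0.4), (1.2, 0.8), (1.8, 1.2)])) == pytest.approx(
            50.0, abs=1e-6
        )

    def test_population_sd_option(self):
        k = karyo([(3.0, 1.0), (4.0, 2.0)])
        assert cvcl(k, sample_sd=False) == pytest.approx(20.0)

    def test_requires_two_chromosomes(self):
        with pytest.raises(ValueError):
            cvcl(karyo([(2.0, 1.0)]))


class TestTML:
    def test_diploid_half_of_somatic_total(self):
        k = karyo([(2.0, 2.0), (2.0, 2.0), (3.0, 3.0), (3.0, 3.0)], ploidy=2)
        assert tml(k) == pytest.approx(10.0)

    def test_tetraploid(self):
        k = karyo([(3.0, 2.0)] * 28, ploidy=4)
        assert tml(k) == pytest.approx(35.0)

    def test_unbalanced_rejected(self):
        k = karyo([(2.0, 2.0)] * 4, ploidy=2)
        k.chromosomes = k.chromosomes[:-1]
        k.unbalanced = True
        with pytest.raises(ValueError):
            tml(k)

    def test_per_genome_split_matches_printed_subrows(self, fx):
        by_genome = tml_by_genome(fx["P. aquatica"])
        assert by_genome["B"] == pytest.approx(49.3, rel=1e-6)
        assert by_genome["C"] == pytest.approx(49.9, rel=1e-6)


class TestOracleEquivalence:
    def test_matches_naive_loop_on_random_karyotypes(self):
        rng = random.Random(20260925)
        for _ in range(300):
            k = random_karyotype(rng)
            assert mca(k) == pytest.approx(mca_oracle(k), rel=1e-9)
            assert cvcl(k) == pytest.approx(cvcl_oracle(k), rel=1e-9)


class TestInvariances:
    def _scaled(self, k, c):
        return Karyotype(
            k.species,
            [
                Chromosome(ch.label, ch.long_arm_um * c, ch.short_arm_um * c, sites=ch.sites)
                for ch in k.chromosomes
            ],
            k.ploidy,
            k.basic_number_x,
        )

    def test_scale_invariance(self):
        rng = random.Random(7)
        for _ in range(50):
            k = random_karyotype(rng)
            c = rng.uniform(0.1, 10.0)
            ks = self._scaled(k, c)
            assert mca(ks) == pytest.approx(mca(k), rel=1e-9)
            assert cvcl(ks) == pytest.approx(cvcl(k), rel=1e-9)
            assert tml(ks) == pytest.approx(tml(k) * c, rel=1e-9)

    def test_permutation_invariance(self):
        rng = random.Random(11)
        for _ in range(50):
            k = random_karyotype(rng)
            shuffled = k.copy()
            rng.shuffle(shuffled.chromosomes)
            assert mca(shuffled) == pytest.approx(mca(k), rel=1e-12)
            assert cvcl(shuffled) == pytest.approx(cvcl(k), rel=1e-12)

    def test_autopolyploidy_invariance(self):
        rng = random.Random(13)
        for _ in range(20):
            k = random_karyotype(rng, n_min=4)
            doubled = autopolyploidize(k, 2)
            assert mca(doubled) == pytest.approx(mca(k), rel=1e-12)
            # duplicating every value leaves the population CV unchanged
            assert cvcl(doubled, sample_sd=False) == pytest.approx(
                cvcl(k, sample_sd=False), rel=1e-12
            )
            assert tml(doubled) == pytest.approx(tml(k), rel=1e-12)


class TestRdnaCounts:
    def test_fixture_counts(self, fx):
        assert count_rdna(fx["P. brachystachys"], RDNAFamily.FIVE_S) == (4, 2)
        assert count_rdna(fx["P. minor"], RDNAFamily.FIVE_S) == (16, 14)

    def test_empty_karyotype(self):
        k = Karyotype("none", [], ploidy=2, basic_number_x=1, unbalanced=True)
        assert count_rdna(k, RDNAFamily.FIVE_S) == (0, 0)

    def test_signals_at_least_bearing(self, fx):
        for k in fx.values():
            for fam in RDNAFamily:
                signals, bearing = count_rdna(k, fam)
                assert signals >= bearing


class TestStatsTable:
    def test_empty_input(self):
        table = stats_table([])
        assert len(table) == 0
        assert list(table.columns)[:2] == ["species", "2n"]

    def test_counts_match_published_table(self, fx, species_names):
        table = stats_table([fx[n] for n in species_names]).set_index("species")
        for name in species_names:
            _, _, _, _, c45, c5, _ = SPECIES_EXPECTED[name]
            assert table.loc[name, "45S"] == f"{c45[0]}/{c45[1]}"
            assert table.loc[name, "5S"] == f"{c5[0]}/{c5[1]}"
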