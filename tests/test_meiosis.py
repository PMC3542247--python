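import math
from random import Random

import numpy as np
import pytest
from scipy import stats as sps

from polymeiosis import (
    ChiasmaProcessConfig,
    ChromosomeSpec,
    CrossQuadrivalent,
    HaploStruct,
    ParallelQuadrivalent,
    TwoBivalents,
    build_cross_quadrivalent,
    build_parallel_quadrivalent,
    decide_configuration,
    do_bivalent,
    do_meiosis,
    expected_quadrivalent_fraction,
    first_division,
    founder_genome,
    pair_telomere,
    sample_gamete,
    second_division,
)
from polymeiosis.meiosis import PAIRINGS, _Chromatid

QUIET = ChiasmaProcessConfig(mean_distance=1e6)  # effectively chiasma-free


def founder_homologs(spec, ploidy=4):
    return founder_genome(0, ploidy, [spec]).homologs[spec.name]


class TestPairTelomere:
    def test_full_preferential_always_matching(self, rng):
        assert all(pair_telomere(1.0, rng) == 0 for _ in range(2000))

    def test_random_pairing_uniform(self, rng):
        n = 30000
        counts = np.bincount([pair_telomere(0.0, rng) for _ in range(n)], minlength=3)
        se = math.sqrt((1 / 3) * (2 / 3) / n)
        for c in counts:
            assert abs(c / n - 1 / 3) < 3 * se

    def test_intermediate_preferential(self, rng):
        # p=0.5: matching pairing probability 0.5 + 0.5/3 = 2/3
        n = 30000
        matching = sum(pair_telomere(0.5, rng) == 0 for _ in range(n))
        se = math.sqrt((2 / 3) * (1 / 3) / n)
        assert abs(matching / n - 2 / 3) < 3 * se

    def test_out_of_range(self, rng):
        with pytest.raises(ValueError):
            pair_telomere(1.5, rng)


class TestExpectedQuadrivalentFraction:
    def test_reference_values(self):
        assert round(expected_quadrivalent_fraction(0.0), 3) == 0.667
        assert round(expected_quadrivalent_fraction(0.25), 3) == 0.625
        assert round(expected_quadrivalent_fraction(0.5), 3) == 0.500
        assert round(expected_quadrivalent_fraction(0.75), 3) == 0.292
        assert expected_quadrivalent_fraction(1.0) == 0.0

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            expected_quadrivalent_fraction(-0.1)


class TestDecideConfiguration:
    def test_diploid_always_bivalent(self, chrom100, rng):
        assert decide_configuration(chrom100, rng, ploidy=2).kind == "bivalent"

    def test_natural_mode_random_pairing(self, chrom100, rng):
        n = 30000
        quads = sum(
            decide_configuration(chrom100, rng).kind != "bivalents" for _ in range(n)
        )
        se = math.sqrt((2 / 3) * (1 / 3) / n)
        assert abs(quads / n - 2 / 3) < 3 * se

    def test_natural_mode_full_preferential(self, rng):
        spec = ChromosomeSpec("1", 100.0, 20.0, pref_pairing=1.0)
        for _ in range(2000):
            config = decide_configuration(spec, rng)
            assert isinstance(config, TwoBivalents)
            assert config.pairing == 0

    def test_forced_fraction(self, rng):
        spec = ChromosomeSpec("1", 100.0, 20.0, quadrivalent_fraction=0.4)
        n = 30000
        quads = sum(decide_configuration(spec, rng).kind != "bivalents" for _ in range(n))
        se = math.sqrt(0.4 * 0.6 / n)
        assert abs(quads / n - 0.4) < 3 * se

    def test_forced_quadrivalent_pairings_differ(self, rng):
        spec = ChromosomeSpec(
            "1", 100.0, 20.0, pref_pairing=0.5, quadrivalent_fraction=1.0
        )
        for _ in range(2000):
            config = decide_configuration(spec, rng)
            assert isinstance(config, CrossQuadrivalent)
            assert config.top != config.bottom

    def test_parallel_fraction(self, chrom100_parallel, rng):
        for _ in range(500):
            assert isinstance(decide_configuration(chrom100_parallel, rng), ParallelQuadrivalent)


class TestBivalentRecombination:
    def test_recombination_matches_haldane(self, chrom100, cfg, rng):
        # Table-level reference: r over 10 cM without interference = 0.0906
        h0, h1 = founder_homologs(chrom100, ploidy=2)
        n = 20000
        rec = tot = 0
        for _ in range(n):
            for unit in do_bivalent(h0, h1, chrom100, cfg, rng):
                for ct in unit:
                    rec += ct.allele_at(45.0) != ct.allele_at(55.0)
                    tot += 1
        r = rec / tot
        se = math.sqrt(0.0906 * (1 - 0.0906) / tot)
        assert abs(r - 0.0906) < 3 * se

    def test_no_chiasmata_no_recombination(self, chrom100, rng):
        h0, h1 = founder_homologs(chrom100, ploidy=2)
        units = do_bivalent(h0, h1, chrom100, QUIET, rng)
        chromatids = [ct for unit in units for ct in unit]
        assert all(len(ct.starts) == 1 for ct in chromatids)

    def test_content_conservation(self, chrom100, cfg, rng):
        h0, h1 = founder_homologs(chrom100, ploidy=2)
        for _ in range(200):
            units = do_bivalent(h0, h1, chrom100, cfg, rng)
            chromatids = [ct for unit in units for ct in unit]
            for pos in (0.0, 20.0, 50.0, 99.0):
                alleles = sorted(ct.allele_at(pos) for ct in chromatids)
                assert alleles == [0, 0, 1, 1]


class TestCrossQuadrivalent:
    def test_identical_pairings_rejected(self, chrom100, cfg, rng):
        homs = founder_homologs(chrom100)
        with pytest.raises(ValueError):
            build_cross_quadrivalent(homs, 1, 1, chrom100, cfg, rng)

    def test_three_founder_mosaics_occur(self, chrom100, cfg, rng):
        homs = founder_homologs(chrom100)
        found = False
        for _ in range(500):
            units, _ = build_cross_quadrivalent(homs, 0, 1, chrom100, cfg, rng)
            for unit in units:
                for ct in unit:
                    if len(set(ct.alleles)) >= 3:
                        found = True
        assert found

    def test_quiet_streams_center_exchange(self, chrom100, rng):
        homs = founder_homologs(chrom100)
        units, exchange = build_cross_quadrivalent(homs, 0, 1, chrom100, QUIET, rng)
        assert exchange == pytest.approx(50.0)
        assert all(len(ct.starts) == 1 for unit in units for ct in unit)

    def test_exchange_point_unimodal_at_center(self, chrom100, cfg, rng):
        homs = founder_homologs(chrom100)
        points = [
            build_cross_quadrivalent(homs, 0, 1, chrom100, cfg, rng)[1]
            for _ in range(5000)
        ]
        hist, _ = np.histogram(points, bins=10, range=(0.0, 100.0))
        center = hist[4] + hist[5]
        assert center > hist[0] + hist[1]
        assert center > hist[8] + hist[9]
        assert np.argmax(hist) in (4, 5)

    def test_content_conservation(self, chrom100, cfg, rng):
        homs = founder_homologs(chrom100)
        for _ in range(100):
            units, _ = build_cross_quadrivalent(homs, 0, 2, chrom100, cfg, rng)
            chromatids = [ct for unit in units for ct in unit]
            for pos in (0.0, 50.0, 99.0):
                assert sorted(ct.allele_at(pos) for ct in chromatids) == [
                    0, 0, 1, 1, 2, 2, 3, 3,
                ]


class TestParallelQuadrivalent:
    def test_four_founder_mosaics_occur(self, chrom100, cfg, rng):
        homs = founder_homologs(chrom100)
        found = False
        for _ in range(500):
            units = build_parallel_quadrivalent(homs, chrom100, cfg, rng)
            for unit in units:
                for ct in unit:
                    if len(set(ct.alleles)) == 4:
                        found = True
        assert found

    def test_content_conservation(self, chrom100, cfg, rng):
        homs = founder_homologs(chrom100)
        for _ in range(100):
            units = build_parallel_quadrivalent(homs, chrom100, cfg, rng)
            chromatids = [ct for unit in units for ct in unit]
            for pos in (0.0, 50.0, 99.0):
                assert sorted(ct.allele_at(pos) for ct in chromatids) == [
                    0, 0, 1, 1, 2, 2, 3, 3,
                ]


class TestFirstDivision:
    def test_quadrivalent_partitions_uniform(self, chrom100, rng):
        config = ParallelQuadrivalent()
        n = 20000
        counts = {}
        for _ in range(n):
            pole0, pole1 = first_division(config, chrom100, rng)
            key = frozenset({frozenset(pole0), frozenset(pole1)})
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 3
        se = math.sqrt((1 / 3) * (2 / 3) / n)
        for c in counts.values():
            assert abs(c / n - 1 / 3) < 3 * se

    def test_two_bivalents_split(self, chrom100, rng):
        for pairing in range(3):
            config = TwoBivalents(pairing)
            for _ in range(300):
                pole0, pole1 = first_division(config, chrom100, rng)
                for i, j in PAIRINGS[pairing]:
                    assert (i in pole0) != (j in pole0)

    def test_paired_centromeres_separates_partners(self, rng):
        spec = ChromosomeSpec("1", 100.0, 20.0, paired_centromeres=True)
        config = CrossQuadrivalent(0, 1, exchange_point=60.0)
        # centromere (20) above the exchange point: top pairing (0,1),(2,3)
        for _ in range(500):
            pole0, pole1 = first_division(config, spec, rng)
            assert (0 in pole0) != (1 in pole0)
            assert (2 in pole0) != (3 in pole0)

    def test_paired_centromeres_bottom_side(self, rng):
        spec = ChromosomeSpec("1", 100.0, 80.0, paired_centromeres=True)
        config = CrossQuadrivalent(0, 1, exchange_point=40.0)
        # centromere below the exchange point: bottom pairing (0,2),(1,3)
        for _ in range(500):
            pole0, _ = first_division(config, spec, rng)
            assert (0 in pole0) != (2 in pole0)
            assert (1 in pole0) != (3 in pole0)

    def test_paired_centromeres_rejected_for_parallel(self, rng):
        spec = ChromosomeSpec("1", 100.0, 20.0, paired_centromeres=True)
        with pytest.raises(ValueError):
            first_division(ParallelQuadrivalent(), spec, rng)


class TestSecondDivision:
    @staticmethod
    def _units():
        h = HaploStruct([(0, 0)])
        return [
            [_Chromatid(h, 0), _Chromatid(h, 0)],
            [_Chromatid(h, 1), _Chromatid(h, 1)],
        ]

    def test_one_chromatid_per_unit(self, rng):
        units = self._units()
        d0, d1 = second_division(units, rng)
        assert len(d0) == len(d1) == 2
        for unit, a, b in zip(units, d0, d1):
            assert {id(a), id(b)} == {id(unit[0]), id(unit[1])}

    def test_orientation_balanced_and_independent(self, rng):
        n = 20000
        first = 0
        joint = np.zeros((2, 2))
        for _ in range(n):
            units = self._units()
            d0, _ = second_division(units, rng)
            o0 = int(d0[0] is units[0][0])
            o1 = int(d0[1] is units[1][0])
            first += o0
            joint[o0, o1] += 1
        se = math.sqrt(0.25 / n)
        assert abs(first / n - 0.5) < 3 * se
        assert sps.chisquare(joint.ravel(), np.full(4, n / 4)).pvalue > 1e-3


class TestDoMeiosis:
    def test_gamete_chromatid_counts(self, chrom100, cfg, rng):
        for ploidy in (2, 4):
            parent = founder_genome(0, ploidy, [chrom100])
            gametes = do_meiosis(parent, [chrom100], cfg, rng)
            assert len(gametes) == 4
            for g in gametes:
                assert len(g.chromatids["1"]) == ploidy // 2

    def test_meiosis_conservation_all_configurations(self, cfg, rng):
        # Every parental homolog allele appears exactly twice among the
        # eight chromatids of the four gametes, at every position.
        spec = ChromosomeSpec("1", 100.0, 20.0, parallel_fraction=0.5)
        parent = founder_genome(0, 4, [spec])
        for _ in range(300):
            gametes = do_meiosis(parent, [spec], cfg, rng)
            chromatids = [ct for g in gametes for ct in g.chromatids["1"]]
            for pos in (0.0, 20.0, 60.0, 99.5):
                assert sorted(ct.allele_at(pos) for ct in chromatids) == [
                    0, 0, 1, 1, 2, 2, 3, 3,
                ]

    def test_bivalent_only_no_double_reduction(self, chrom100_bivalent, cfg, rng):
        parent = founder_genome(0, 4, [chrom100_bivalent])
        for _ in range(2000):
            gametes = do_meiosis(parent, [chrom100_bivalent], cfg, rng)
            for g in gametes:
                a, b = g.chromatids["1"]
                for pos in (0.0, 20.0, 50.0, 99.5):
                    assert a.allele_at(pos) != b.allele_at(pos)

    def test_gamete_centromeres_from_different_parents(self, cfg, rng):
        # Tetraploid invariant across all configurations: the founder
        # alleles at the centromere differ between a gamete's chromatids.
        spec = ChromosomeSpec("1", 100.0, 20.0, parallel_fraction=0.5)
        parent = founder_genome(0, 4, [spec])
        for _ in range(1500):
            for g in do_meiosis(parent, [spec], cfg, rng):
                a, b = g.chromatids["1"]
                assert a.allele_at(20.0) != b.allele_at(20.0)

    def test_chromosome_assortment_independent(self, cfg, rng):
        # Two chromosomes assort independently into gametes.
        specs = [
            ChromosomeSpec("1", 100.0, 20.0, quadrivalent_fraction=0.0),
            ChromosomeSpec("2", 100.0, 20.0, quadrivalent_fraction=0.0),
        ]
        parent = founder_genome(0, 2, specs)
        n = 4000
        joint = np.zeros((2, 2))
        for _ in range(n):
            g = do_meiosis(parent, specs, cfg, rng)[0]
            joint[g.chromatids["1"][0].allele_at(20.0), g.chromatids["2"][0].allele_at(20.0)] += 1
        assert sps.chisquare(joint.ravel(), np.full(4, n / 4)).pvalue > 1e-3


class TestSampleGamete:
    def test_uniform_choice(self, chrom100, cfg, rng):
        parent = founder_genome(0, 2, [chrom100])
        gametes = do_meiosis(parent, [chrom100], cfg, rng)
        n = 20000
        counts = [0] * 4
        index = {id(g): i for i, g in enumerate(gametes)}
        for _ in range(n):
            counts[index[id(sample_gamete(gametes, rng))]] += 1
        se = math.sqrt(0.25 * 0.75 / n)
        for c in counts:
            assert abs(c / n - 0.25) < 3 * se

    def test_deterministic_under_seed(self, chrom100, cfg):
        parent = founder_genome(0, 2, [chrom100])
        gametes = do_meiosis(parent, [chrom100], cfg, Random(1))
        picks1 = [id(sample_gamete(gametes, Random(7))) for _ in range(10)]
        picks2 = [id(sample_gamete(gametes, Random(7))) for _ in range(10)]
        assert picks1 == picks2

    def test_requires_four(self, rng):
        with pytest.raises(ValueError):
            sample_gamete([], rng)
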