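"""Generative model: crossover sampling, chromatid assignment, tetrads, F2s."""

import numpy as np
import pytest
from scipy import stats

import meiocross as mc
from meiocross.simulate import (
    CrossoverEvent,
    MeiosisOutcome,
    chromatid_origins,
    sample_class1_positions,
    sample_class2_positions,
)


class TestClassOneSampling:
    def test_zero_map_length_always_empty(self):
        chrom = mc.Chromosome("c", 10.0)
        model = mc.CrossoverModel(class1_map_length_cm=0.0)
        for seed in range(20):
            pos, rej = sample_class1_positions(chrom, model, seed)
            assert pos.size == 0 and rej == 0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(mc.InputError):
            mc.CrossoverModel(class1_map_length_cm=-5.0)
        with pytest.raises(mc.InputError):
            mc.CrossoverModel(interference_shape_nu=0.5)

    def test_nu_one_counts_are_poisson(self, rng):
        # 100 cM map -> bivalent rate 2 events per meiosis; nu = 1 is Poisson
        chrom = mc.Chromosome("c", 10.0)
        model = mc.CrossoverModel(class1_map_length_cm=100.0, interference_shape_nu=1.0)
        counts = np.array(
            [sample_class1_positions(chrom, model, rng)[0].size for _ in range(10000)]
        )
        kmax = 8
        observed = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        probs = stats.poisson.pmf(np.arange(kmax), 2.0)
        probs = np.append(probs, 1.0 - probs.sum())
        chi2, p = stats.chisquare(observed, probs * counts.size)
        assert p > 0.01

    def test_obligate_guarantees_at_least_one(self, rng):
        chrom = mc.Chromosome("c", 10.0)
        model = mc.CrossoverModel(
            class1_map_length_cm=20.0, interference_shape_nu=1.0, obligate_class1=True
        )
        sizes, rejections = zip(
            *(
                (pos.size, rej)
                for pos, rej in (
                    sample_class1_positions(chrom, model, rng) for _ in range(10000)
                )
            )
        )
        assert min(sizes) == 1
        # a 20 cM map is crossover-free ~67% of the time, so rejections occur
        assert sum(rejections) > 0

    def test_positions_inside_map(self, rng):
        chrom = mc.Chromosome("c", 10.0)
        model = mc.CrossoverModel(class1_map_length_cm=80.0, interference_shape_nu=3.0)
        for _ in range(200):
            pos, _ = sample_class1_positions(chrom, model, rng)
            assert np.all((pos > 0) & (pos < 80.0))


class TestClassTwoSampling:
    def test_zero_mean_empty(self, rng):
        chrom = mc.Chromosome("c", 10.0)
        model = mc.CrossoverModel(class2_mean_per_bivalent=0.0)
        assert sample_class2_positions(chrom, model, rng).size == 0

    def test_mean_recovery(self, rng):
        chrom = mc.Chromosome("c", 10.0)
        model = mc.CrossoverModel(class2_mean_per_bivalent=0.30)
        counts = np.array(
            [sample_class2_positions(chrom, model, rng).size for _ in range(10000)]
        )
        se = np.sqrt(0.30 / counts.size)
        assert abs(counts.mean() - 0.30) < 3 * se

    def test_fancm_attenuation_removes_excess_in_hybrids(self):
        full = mc.preset_model("fancm", context="hybrid", hybrid_attenuation=0.0)
        assert full.effective_class2_mean() == pytest.approx(0.30)
        none = mc.preset_model("fancm", context="hybrid", hybrid_attenuation=1.0)
        inbred = mc.preset_model("fancm", context="inbred")
        assert none.effective_class2_mean() == pytest.approx(
            inbred.effective_class2_mean()
        )


class TestChromatidAssignment:
    def test_single_event_pairs_uniform(self, rng):
        events = mc.assign_chromatids(np.full(100000, 1.0), np.ones(100000), rng)
        pairs = [e.chromatids for e in events]
        for pair in ((0, 2), (0, 3), (1, 2), (1, 3)):
            freq = sum(p == pair for p in pairs) / len(pairs)
            assert abs(freq - 0.25) < 0.005

    def test_two_event_strand_sharing(self, rng):
        # enumerating the 16 equally likely pair-of-pairs: share 0/1/2
        # chromatids with probability 1/4, 1/2, 1/4
        n = 30000
        shared = np.empty(n)
        for i in range(n):
            events = mc.assign_chromatids([1.0, 2.0], [1, 1], rng)
            a, b = set(events[0].chromatids), set(events[1].chromatids)
            shared[i] = len(a & b)
        for k, expected in ((0, 0.25), (1, 0.5), (2, 0.25)):
            freq = (shared == k).mean()
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(freq - expected) < 3 * se

    def test_no_events(self, rng):
        assert mc.assign_chromatids([], [], rng) == []

    def test_event_pairs_span_both_homologs(self, rng, genome):
        model = mc.preset_model("wild_type", genome)
        outcome = mc.simulate_meiosis(genome, model, rng)
        for name, events in outcome.events.items():
            length = genome.chromosome(name).length_mb
            for e in events:
                assert e.chromatids[0] in (0, 1) and e.chromatids[1] in (2, 3)
                assert 0.0 <= e.position_mb <= length


class TestBivalents:
    def test_sds_gives_five_univalent_pairs(self, rng, genome):
        model = mc.preset_model("sds", genome)
        for _ in range(50):
            assert mc.count_bivalents(mc.simulate_meiosis(genome, model, rng)) == (0, 5)

    def test_obligate_wild_type_always_five_bivalents(self, rng, genome):
        model = mc.preset_model("wild_type", genome)
        for _ in range(300):
            assert mc.count_bivalents(mc.simulate_meiosis(genome, model, rng)) == (5, 0)

    def test_zmm_bivalent_mean_matches_poisson_prediction(self, rng, genome):
        # class-II-only, mean 0.30 per pair: E[bivalents] = 5(1 - e^-0.3) = 1.296
        model = mc.preset_model("zmm", genome)
        n = 4000
        biv = np.array(
            [mc.count_bivalents(mc.simulate_meiosis(genome, model, rng))[0] for _ in range(n)]
        )
        p = 1.0 - np.exp(-0.3)
        expected = 5 * p
        se = np.sqrt(5 * p * (1 - p) / n)
        assert abs(biv.mean() - expected) < 3 * se


def _manual_outcome(genome, events_chr1):
    events = {c.name: [] for c in genome.chromosomes}
    events[genome.chromosomes[0].name] = events_chr1
    return MeiosisOutcome(events)


class TestTetradConstruction:
    def test_no_crossovers_gives_parental_ditype_pattern(self, genome):
        panel = mc.default_ftl_panel(genome)
        pattern = mc.make_tetrad(_manual_outcome(genome, []), panel)
        assert mc.classify_tetrad(pattern) == "A"
        assert pattern == ((1, 1, 1), (1, 1, 1), (0, 0, 0), (0, 0, 0))

    def test_single_crossover_in_first_interval(self, genome):
        panel = mc.default_ftl_panel(genome)  # markers at 2, 6, 10 Mb
        outcome = _manual_outcome(genome, [CrossoverEvent(4.0, 1, (0, 2))])
        pattern = mc.make_tetrad(outcome, panel)
        assert mc.interval_tetrad_type(pattern, "I1") == "T"
        assert mc.interval_tetrad_type(pattern, "I2") == "PD"
        assert mc.classify_tetrad(pattern) == "C"

    def test_triple_must_be_collinear(self, genome):
        markers = [
            mc.Marker("m1", "chr1", 2.0, "ftl_fluorescent"),
            mc.Marker("m2", "chr2", 6.0, "ftl_fluorescent"),
            mc.Marker("m3", "chr1", 10.0, "ftl_fluorescent"),
        ]
        panel = mc.MarkerPanel(markers)
        with pytest.raises(mc.InputError):
            mc.make_tetrad(_manual_outcome(genome, []), panel)

    def test_three_strand_double_is_double_tetratype(self, genome):
        # junctions resolve on the original molecules: a three-strand
        # double crossover is a tetratype in both intervals
        panel = mc.default_ftl_panel(genome)
        outcome = _manual_outcome(
            genome,
            [CrossoverEvent(4.0, 1, (0, 2)), CrossoverEvent(8.0, 1, (1, 2))],
        )
        pattern = mc.make_tetrad(outcome, panel)
        assert mc.interval_tetrad_type(pattern, "I1") == "T"
        assert mc.interval_tetrad_type(pattern, "I2") == "T"

    def test_two_to_two_segregation_everywhere(self, rng, genome):
        model = mc.preset_model("figl1_fancm", genome)
        positions = np.linspace(0.1, 30.0, 25)
        for _ in range(100):
            outcome = mc.simulate_meiosis(genome, model, rng)
            origins = chromatid_origins(outcome.events["chr1"], positions)
            assert np.all(origins.sum(axis=0) == 2)


class TestF2Population:
    def test_zero_crossover_preset_is_nonrecombinant(self, rng, genome):
        model = mc.preset_model("sds", genome)
        panel = mc.MarkerPanel.snp_grid(genome, 3.0)
        matrix = mc.make_f2_population(40, genome, model, panel, rng)
        assert (mc.count_crossovers(matrix) == 0).all()

    def test_mendelian_segregation(self, rng, one_chrom):
        model = mc.preset_model("sds", one_chrom)
        panel = mc.MarkerPanel.snp_grid(one_chrom, 8.0)
        matrix = mc.make_f2_population(10000, one_chrom, model, panel, rng)
        for marker in matrix.genotypes.columns:
            observed = matrix.genotypes[marker].value_counts().reindex(
                [0.0, 1.0, 2.0], fill_value=0
            )
            _, p = stats.chisquare(observed, np.array([0.25, 0.5, 0.25]) * len(matrix.genotypes))
            assert p > 0.01

    def test_dense_markers_recover_co_rate(self, rng):
        # 400 cM of gamete map -> 4 breakpoints per gamete, 8 per plant
        genome = mc.single_chromosome_genome(20.0)
        model = mc.CrossoverModel(class1_map_length_cm=400.0, interference_shape_nu=1.0)
        panel = mc.MarkerPanel.snp_grid(genome, 0.05, flush_ends=True)
        matrix = mc.make_f2_population(400, genome, model, panel, rng)
        counts = mc.count_crossovers(matrix)
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - 8.0) < 3 * se

    def test_missing_rate(self, rng, one_chrom):
        model = mc.preset_model("sds", one_chrom)
        panel = mc.MarkerPanel.snp_grid(one_chrom, 2.0)
        matrix = mc.make_f2_population(300, one_chrom, model, panel, rng, missing_rate=0.1)
        frac = matrix.genotypes.isna().to_numpy().mean()
        assert 0.06 < frac < 0.14


class TestPresetOrdering:
    def test_double_mutant_exceeds_singles_in_inbreds(self, genome):
        def mean_co(preset, seed):
            r = np.random.default_rng(seed)
            model = mc.preset_model(preset, genome)
            return np.mean(
                [
                    sum(len(e) for e in mc.simulate_meiosis(genome, model, r).events.values())
                    for _ in range(400)
                ]
            )

        wt = mean_co("wild_type", 1)
        figl1 = mean_co("figl1", 2)
        fancm = mean_co("fancm", 3)
        double = mean_co("figl1_fancm", 4)
        assert wt < figl1 < double and wt < fancm < double

    def test_fancm_effect_suppressed_in_hybrids(self, genome):
        inbred = mc.preset_model("fancm", genome, context="inbred")
        hybrid = mc.preset_model("fancm", genome, context="hybrid")
        wt = mc.preset_model("wild_type", genome)
        assert hybrid.effective_class2_mean() < inbred.effective_class2_mean()
        assert hybrid.effective_class2_mean() > wt.effective_class2_mean()
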