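import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from introndelay.models import (
    MIN_INTRON,
    CellCycleSchedule,
    ConfigurationError,
    GeneModel,
    InputError,
    PhylogenyConfig,
    SimulationConfig,
    TranscriptPool,
)
from introndelay.synthetic_data import (
    evolve_orthologous_introns,
    make_genome,
    make_planted_delay_matrix,
    pools_to_expression,
    sample_reads,
    simulate_timecourse,
)
from introndelay.conservation_analysis import cv_star
from introndelay.coverage_analysis import windowed_coverage


def brute_force_completions(length, schedule, rate, v, t_end, rng, dt=0.01):
    """Fine-step Monte Carlo of one gene: initiate with prob rate*dt per step
    during eligible interphases, advance positions by v*dt, abort everything
    at each mitosis entry, count transcripts that reach full length."""
    positions = []
    completed = 0
    for cycle, phase, t0, t1 in schedule.segments():
        if t0 >= t_end:
            break
        if phase == "mitosis":
            positions = []
            continue
        t = t0
        while t < min(t1, t_end):
            positions = [p + v * dt for p in positions]
            done = [p for p in positions if p >= length]
            completed += len(done)
            positions = [p for p in positions if p < length]
            if cycle >= schedule.zga_cycle and rng.random() < rate * dt:
                positions.append(0.0)
            t += dt
    return completed


class TestMakeGenome:
    def test_zero_genes_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            make_genome(0)

    def test_deterministic_for_fixed_seed(self):
        g1, c1 = make_genome(100, seed=1)
        g2, c2 = make_genome(100, seed=1)
        assert [g.exons for g in g1] == [g.exons for g in g2]
        assert (c1 == c2).all().all()
        g3, _ = make_genome(100, seed=2)
        assert [g.exons for g in g1] != [g.exons for g in g3]

    def test_structures_satisfy_invariants(self):
        genes, _ = make_genome(300, seed=3)
        for g in genes:
            assert all(e > s for s, e in g.exons)
            assert all(il >= MIN_INTRON for il in g.intron_lengths)
            assert g.exonic_length <= g.primary_length

    def test_long_fraction_matches_lognormal_tail(self):
        # oracle: P(L >= 5 kb) for a log-normal with median 2.5 kb, sigma 1
        expected = 1.0 - sps.norm.cdf(np.log(5000 / 2500) / 1.0)
        genes, _ = make_genome(2000, seed=4)
        frac = np.mean([g.primary_length >= 5000 for g in genes])
        assert 0.15 <= frac <= 0.45
        assert abs(frac - expected) < 0.05

    def test_both_classes_and_origins_present(self):
        genes, classes = make_genome(40, seed=5)
        lengths = np.array([g.primary_length for g in genes])
        assert (lengths < 5000).any() and (lengths >= 5000).any()
        assert set(classes["origin"]) == {"maternal", "zygotic"}

    def test_invalid_length_spec(self):
        with pytest.raises(ConfigurationError):
            make_genome(10, length_spec={"sigma": -1.0})


class TestSimulateTimecourse:
    def test_gene_longer_than_completable_bound_never_completes(self, default_schedule):
        gene = GeneModel("g", "chr2L", "+", ((0, 15000),), origin="zygotic")
        # before cycle 14, max interphase 13 min: 15000 > 1400*13
        cfg = SimulationConfig(
            initiation_rate=10.0, sample_times=(96.0, 110.0, 126.0), seed=0
        )
        pools = simulate_timecourse([gene], default_schedule, cfg, seed=0)
        for t, pool in pools.items():
            assert pool.complete_count("g") == 0
            assert pool.completed[0] == 0
            assert (pool.nascent_positions < 15000).all()

    def test_long_interphase_allows_completion_matches_brute_force(self):
        # one 60-min interphase after short cycles; 15 kb gene finishes there
        cycles = tuple([(i, 6.0, 3.0) for i in range(1, 8)] + [(8, 60.0, 3.0)])
        sched = CellCycleSchedule(cycles=cycles, zga_cycle=1)
        gene = GeneModel("g", "chr2L", "+", ((0, 15000),), origin="zygotic")
        cfg = SimulationConfig(
            initiation_rate=1.0,
            zygotic_decay_rate=0.0,
            sample_times=(float(sched.total_duration),),
            independent_timepoints=False,
        )
        n_rep = 60
        sim_counts = [
            simulate_timecourse([gene], sched, cfg, seed=s)[sched.total_duration]
            .complete_count("g")
            for s in range(n_rep)
        ]
        rng = np.random.default_rng(123)
        brute = [
            brute_force_completions(
                15000, sched, 1.0, 1400.0, sched.total_duration, rng
            )
            for _ in range(n_rep)
        ]
        # analytic expectation: initiations in the first 60 - 15000/1400 min
        expected = 60.0 - 15000.0 / 1400.0
        assert np.mean(sim_counts) == pytest.approx(expected, rel=0.15)
        assert np.mean(sim_counts) == pytest.approx(np.mean(brute), rel=0.2)
        assert all(c > 0 for c in sim_counts)

    def test_maternal_pool_constant_with_zero_decay(self, default_schedule):
        gene = GeneModel("g", "chr2L", "+", ((0, 2000),), origin="maternal")
        cfg = SimulationConfig(
            maternal_decay_rate=0.0,
            maternal_abundance=80.0,
            sample_times=(10.0, 96.0, 185.0),
            independent_timepoints=False,
        )
        pools = simulate_timecourse([gene], default_schedule, cfg, seed=1)
        counts = {t: p.complete_count("g") for t, p in pools.items()}
        assert len(set(counts.values())) == 1
        assert counts[10.0] > 0

    def test_zygotic_genes_silent_before_zga(self, default_schedule):
        genes, _ = make_genome(50, seed=6)
        # cycle 8 starts at t=63; sample just before
        cfg = SimulationConfig(sample_times=(62.0,), independent_timepoints=False)
        pool = simulate_timecourse(genes, default_schedule, cfg, seed=2)[62.0]
        zyg = [i for i, g in enumerate(genes) if g.origin == "zygotic"]
        assert all(pool.complete[i] == 0 for i in zyg)
        assert all(pool.initiated[i] == 0 for i in zyg)
        assert not np.isin(pool.nascent_gene_index, zyg).any()

    def test_mass_balance_initiated_equals_completed_plus_aborted_plus_nascent(
        self, default_schedule
    ):
        genes, _ = make_genome(80, seed=7)
        cfg = SimulationConfig(sample_times=(96.0, 145.0, 185.0))
        pools = simulate_timecourse(genes, default_schedule, cfg, seed=3)
        for pool in pools.values():
            nascent = np.bincount(pool.nascent_gene_index, minlength=len(genes))
            np.testing.assert_array_equal(
                pool.initiated, pool.completed + pool.aborted + nascent
            )

    def test_deterministic_under_seed(self, default_schedule):
        genes, _ = make_genome(30, seed=8)
        cfg = SimulationConfig(sample_times=(96.0, 160.0))
        a = simulate_timecourse(genes, default_schedule, cfg, seed=9)
        b = simulate_timecourse(genes, default_schedule, cfg, seed=9)
        for t in a:
            np.testing.assert_array_equal(a[t].complete, b[t].complete)
            np.testing.assert_array_equal(a[t].nascent_positions, b[t].nascent_positions)

    def test_sample_time_outside_schedule_rejected(self, default_schedule):
        genes, _ = make_genome(5, seed=1)
        cfg = SimulationConfig(sample_times=(1000.0,))
        with pytest.raises(InputError):
            simulate_timecourse(genes, default_schedule, cfg)

    def test_empty_gene_list_rejected(self, default_schedule):
        with pytest.raises(ConfigurationError):
            simulate_timecourse([], default_schedule, SimulationConfig())


def _nascent_pool(gene, positions):
    n = len(positions)
    return TranscriptPool(
        time=0.0,
        gene_ids=(gene.gene_id,),
        complete=np.array([0]),
        nascent_gene_index=np.zeros(n, dtype=np.int64),
        nascent_positions=np.asarray(positions, dtype=float),
        initiated=np.array([n]),
        completed=np.array([0]),
        aborted=np.array([0]),
    )


def _complete_pool(gene, count):
    return TranscriptPool(
        time=0.0,
        gene_ids=(gene.gene_id,),
        complete=np.array([count]),
        nascent_gene_index=np.empty(0, dtype=np.int64),
        nascent_positions=np.empty(0),
        initiated=np.array([count]),
        completed=np.array([count]),
        aborted=np.array([0]),
    )


class TestSampleReads:
    def test_polya_reads_contained_in_exons(self, single_exon_gene):
        pool = _complete_pool(single_exon_gene, 50)
        cfg = SimulationConfig(library_mode="polyA", reads_per_timepoint=2000)
        reads = sample_reads(pool, [single_exon_gene], cfg, seed=0)
        assert len(reads) == 2000
        assert (reads["start"] >= 1000).all() and (reads["end"] <= 6000).all()
        assert (reads["strand"] == "+").all()

    def test_polya_ignores_nascent_transcripts(self, single_exon_gene):
        pool = _nascent_pool(single_exon_gene, np.linspace(100, 4900, 50))
        cfg = SimulationConfig(library_mode="polyA", reads_per_timepoint=1000)
        reads = sample_reads(pool, [single_exon_gene], cfg, seed=0)
        assert len(reads) == 0

    def test_total_mode_nascent_coverage_is_triangular(self, single_exon_gene):
        # uniform polymerase positions -> read-start density ~ (1 - x/L)
        rng = np.random.default_rng(11)
        pool = _nascent_pool(single_exon_gene, rng.uniform(60, 5000, size=20000))
        cfg = SimulationConfig(
            library_mode="total", reads_per_timepoint=200_000, read_length=50
        )
        reads = sample_reads(pool, [single_exon_gene], cfg, seed=1)
        prof = windowed_coverage(reads, single_exon_gene)
        centers = (np.arange(10) + 0.5) * 500
        triangle = (1 - centers / 5000) / (1 - centers[0] / 5000)
        assert np.max(np.abs(prof.fractional - triangle)) < 0.05

    def test_reads_respect_exon_boundaries_multi_exon(self):
        g = GeneModel("g", "chr2L", "+", ((0, 300), (500, 900)), origin="maternal")
        pool = _complete_pool(g, 20)
        cfg = SimulationConfig(library_mode="polyA", reads_per_timepoint=3000)
        reads = sample_reads(pool, [g], cfg, seed=2)
        inside_first = (reads["start"] >= 0) & (reads["end"] <= 300)
        inside_second = (reads["start"] >= 500) & (reads["end"] <= 900)
        assert (inside_first | inside_second).all()

    def test_strand_symmetry_exact(self):
        # mirror-image genes yield identical transcript-offset profiles
        plus = GeneModel("p", "chr2L", "+", ((1000, 3000), (3100, 6100)))
        offset = 10000
        m_exons = tuple(
            sorted((offset - e, offset - s) for s, e in plus.exons)
        )
        minus = GeneModel("m", "chr2L", "-", m_exons)
        cfg = SimulationConfig(library_mode="total", reads_per_timepoint=20000)
        rng = np.random.default_rng(5)
        positions = rng.uniform(100, 5000, size=500)
        rp = sample_reads(_nascent_pool(plus, positions), [plus], cfg, seed=7)
        rm = sample_reads(_nascent_pool(minus, positions), [minus], cfg, seed=7)
        pp = windowed_coverage(rp, plus)
        pm = windowed_coverage(rm, minus)
        np.testing.assert_allclose(pp.fractional, pm.fractional)

    def test_empty_pool_gives_empty_table(self, single_exon_gene):
        pool = _complete_pool(single_exon_gene, 0)
        reads = sample_reads(pool, [single_exon_gene], SimulationConfig(), seed=0)
        assert len(reads) == 0

    def test_read_length_longer_than_exons_rejected(self):
        g = GeneModel("g", "chr2L", "+", ((0, 40),))
        pool = _complete_pool(g, 5)
        cfg = SimulationConfig(read_length=50, reads_per_timepoint=10)
        with pytest.raises(InputError):
            sample_reads(pool, [g], cfg, seed=0)


class TestEvolveOrthologousIntrons:
    def test_zero_sigma_constrained_genes_identical_across_species(self):
        genes, _ = make_genome(50, seed=10)
        multi = [g for g in genes if g.n_introns > 0]
        phylo = PhylogenyConfig(sigma_neutral=0.5, sigma_constrained=0.0)
        tab = evolve_orthologous_introns(
            genes, phylo, constrained_ids={g.gene_id for g in genes}
        )
        for g in multi:
            row = tab.loc[g.gene_id]
            assert row.nunique() == 1
            assert row.iloc[0] == sum(g.intron_lengths)

    def test_single_species_returns_input_lengths(self):
        genes, _ = make_genome(30, seed=11)
        phylo = PhylogenyConfig(species=("melanogaster",), branch_lengths=(0.0,))
        tab = evolve_orthologous_introns(genes, phylo)
        for g in genes:
            assert tab.loc[g.gene_id, "melanogaster"] == sum(g.intron_lengths)

    def test_constrained_genes_have_lower_cv_star(self):
        genes, _ = make_genome(400, seed=12)
        multi = [g.gene_id for g in genes if g.n_introns > 0]
        constrained = set(multi[: len(multi) // 2])
        phylo = PhylogenyConfig(sigma_neutral=0.5, sigma_constrained=0.01, seed=13)
        tab = evolve_orthologous_introns(genes, phylo, constrained_ids=constrained)
        tab = tab.loc[multi]
        cvs = tab.apply(lambda row: cv_star(row.values), axis=1)
        med_c = cvs[[g in constrained for g in cvs.index]].median()
        med_n = cvs[[g not in constrained for g in cvs.index]].median()
        assert med_c < med_n

    def test_unknown_constrained_id_rejected(self):
        genes, _ = make_genome(5, seed=1)
        with pytest.raises(InputError):
            evolve_orthologous_introns(genes, PhylogenyConfig(), {"nope"})

    def test_min_intron_floor_respected(self):
        genes, _ = make_genome(100, seed=14)
        phylo = PhylogenyConfig(sigma_neutral=2.0, sigma_constrained=0.01, seed=15)
        tab = evolve_orthologous_introns(genes, phylo)
        multi = [g for g in genes if g.n_introns > 0]
        for g in multi:
            assert (tab.loc[g.gene_id] >= phylo.min_intron).all()


class TestPlantedDelayMatrix:
    def test_delay_planted_only_above_threshold(self):
        mat, lengths = make_planted_delay_matrix(n_genes=2000, seed=16)
        delayed = lengths >= 5000
        early_gap = mat.loc[delayed, "t0"].mean() - mat.loc[~delayed, "t0"].mean()
        late_gap = mat.loc[delayed, "t5"].mean() - mat.loc[~delayed, "t5"].mean()
        assert early_gap < -2.0
        assert abs(late_gap) < 0.3
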