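"""Generator correctness: every simulator must match its own ground truth."""

import numpy as np
import pytest

from hybridpaint import simdata
from hybridpaint.models import m01_graph
from hybridpaint.popgen import compute_f4
from hybridpaint.quantseq import GeneModel
from hybridpaint.rearrange import RearrangementCharacterMatrix, rank_topologies, enumerate_rooted_topologies


def _diff(a: str, b: str) -> float:
    x = np.frombuffer(a.encode(), dtype="S1")
    y = np.frombuffer(b.encode(), dtype="S1")
    return float(np.mean(x != y))


class TestLineageSequences:
    def test_zero_branch_yields_identical_sequences(self):
        cfg = simdata.SimConfig(seed=1, sequence_length=10_000,
                                n_strains_per_lineage=1, within_lineage_time=0.0)
        seqs, _, _ = simdata.simulate_lineage_sequences(cfg, tree="(A:0.0,B:0.0);")
        assert seqs["A_1"] == seqs["B_1"]

    def test_saturation_approaches_three_quarters(self):
        cfg = simdata.SimConfig(seed=2, sequence_length=100_000,
                                n_strains_per_lineage=1, within_lineage_time=0.0)
        seqs, _, _ = simdata.simulate_lineage_sequences(cfg, tree="(A:50.0,B:50.0);")
        p = _diff(seqs["A_1"], seqs["B_1"])
        sd = np.sqrt(0.75 * 0.25 / 100_000)
        assert abs(p - 0.75) < 3 * sd

    def test_jc69_expectation_over_replicate_pairs(self):
        # mean observed difference at p_expected = 0.02 within 3 SD over 100 pairs
        p_expected = 0.02
        t = -0.75 * np.log1p(-4 * p_expected / 3)  # total path time
        L, n_pairs = 2000, 100
        diffs = []
        for i in range(n_pairs):
            cfg = simdata.SimConfig(seed=1000 + i, sequence_length=L,
                                    n_strains_per_lineage=1, within_lineage_time=0.0)
            seqs, _, _ = simdata.simulate_lineage_sequences(
                cfg, tree=f"(A:{t / 2},B:{t / 2});")
            diffs.append(_diff(seqs["A_1"], seqs["B_1"]))
        sd = np.sqrt(p_expected * (1 - p_expected) / (L * n_pairs))
        assert abs(np.mean(diffs) - p_expected) < 3 * sd

    def test_fixed_seed_reproduces_identical_output(self, small_config):
        s1, m1, _ = simdata.simulate_lineage_sequences(small_config)
        s2, m2, _ = simdata.simulate_lineage_sequences(small_config)
        assert s1 == s2 and m1 == m2

    def test_polytomy_rejected(self, small_config):
        with pytest.raises(ValueError, match="polytom"):
            simdata.simulate_lineage_sequences(small_config, tree="(A:1,B:1,C:1);")


class TestHybridMosaic:
    def test_zero_donor_fraction_copies_parent_a(self, rng):
        cfg = simdata.SimConfig(seed=3, hybrid_donor_fraction=0.0)
        pa, pb = "ACGT" * 1000, "TGCA" * 1000
        hybrid, truth = simdata.simulate_hybrid_mosaic(pa, pb, cfg, rng=rng)
        assert hybrid == pa
        assert len(truth) == 1 and truth[0].donor == "parentA"
        assert (truth[0].start, truth[0].end) == (0, len(pa))

    def test_realized_fraction_and_block_count(self, rng):
        L, mean_block = 1_000_000, 10_000
        cfg = simdata.SimConfig(seed=4, hybrid_donor_fraction=0.5,
                                mean_block_length=mean_block)
        pa, pb = "A" * L, "C" * L
        hybrid, truth = simdata.simulate_hybrid_mosaic(pa, pb, cfg, rng=rng)
        frac = hybrid.count("C") / L
        # ~100 B-blocks of 10 kb in 1 Mb at fraction 0.5; binomial-ish noise
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / (L / mean_block / 2))
        n_b_blocks = sum(1 for s in truth if s.donor == "parentB")
        assert 50 <= n_b_blocks <= 150
        # truth tiles the chromosome exactly
        assert truth[0].start == 0 and truth[-1].end == L
        for a, b in zip(truth, truth[1:]):
            assert a.end == b.start and a.donor != b.donor

    def test_halving_mean_block_halves_median_length(self):
        L = 2_000_000
        pa, pb = "A" * L, "C" * L
        medians = []
        for mean_block in (10_000, 5_000):
            cfg = simdata.SimConfig(seed=5, hybrid_donor_fraction=0.5,
                                    mean_block_length=mean_block)
            _h, truth = simdata.simulate_hybrid_mosaic(
                pa, pb, cfg, rng=np.random.default_rng(5))
            lengths = [s.length for s in truth if s.donor == "parentB"]
            medians.append(np.median(lengths))
        assert medians[0] / medians[1] == pytest.approx(2.0, rel=0.35)

    def test_unequal_parents_rejected(self, rng):
        cfg = simdata.SimConfig(seed=6)
        with pytest.raises(ValueError, match="equal length"):
            simdata.simulate_hybrid_mosaic("AAAA", "CC", cfg, rng=rng)


class TestBlockPermutations:
    TOPO = ((("B", ("D1", "D2")), ("Cs", "C")), "A")

    def test_no_events_identity(self):
        perms, matrix = simdata.simulate_block_permutations(self.TOPO, [])
        for p in perms:
            assert p.chromosomes == [list(range(1, 11)),
                                     list(range(11, 21)),
                                     list(range(21, 31))]
        assert matrix.shape[1] == 0

    def test_single_inversion_shared_by_clade(self):
        clade = frozenset({"Cs", "D1", "D2"})  # not a clade of TOPO -> use one that is
        clade = frozenset({"D1", "D2"})
        ev = simdata.RearrangementEvent("inversion", clade, (3, 4))
        perms, matrix = simdata.simulate_block_permutations(self.TOPO, [ev])
        by_name = {p.genome: p for p in perms}
        for g in ("D1", "D2"):
            assert by_name[g].chromosomes[0][2:4] == [-4, -3]
        for g in ("A", "B", "C", "Cs"):
            assert by_name[g].chromosomes[0][2:4] == [3, 4]
        assert matrix[("inversion", (3, 4))].to_dict() == {
            "A": 0, "B": 0, "C": 0, "Cs": 0, "D1": 1, "D2": 1}

    def test_truth_characters_score_planted_event_count(self, rng):
        events = simdata.random_rearrangement_events(
            self.TOPO, 5, (10, 10, 10), rng, reference="A")
        _perms, truth = simdata.simulate_block_permutations(self.TOPO, events)
        matrix = RearrangementCharacterMatrix.from_table(truth)
        topologies = enumerate_rooted_topologies(sorted(truth.index))
        scores = rank_topologies(topologies, matrix)
        from hybridpaint.rearrange import to_newick
        true_score = next(s for s in scores if s.topology == to_newick(self.TOPO))
        assert true_score.total_changes == 5
        assert true_score.total_changes == scores[0].total_changes

    def test_overlapping_inversions_on_one_branch_rejected(self):
        clade = frozenset({"D1", "D2"})
        evs = [simdata.RearrangementEvent("inversion", clade, (3, 4)),
               simdata.RearrangementEvent("inversion", clade, (4, 5))]
        with pytest.raises(ValueError, match="ambiguous"):
            simdata.simulate_block_permutations(self.TOPO, evs)


class TestGrowthSimulation:
    def test_noiseless_truth_matches_closed_form(self):
        times = np.arange(0.0, 81.0, 4.0)
        truth = simdata.logistic_true_metrics(4.0, 0.2, 40.0, times)
        assert truth["MS"] == pytest.approx(0.2 * 4.0 / 4.0)
        # numeric integral of the normalized logistic as cross-check
        tt = np.linspace(0, 80, 20001)
        y = 4.0 / (1 + np.exp(-0.2 * (tt - 40.0)))
        y -= y[0]
        assert truth["AUC"] == pytest.approx(np.trapezoid(y, tt), rel=1e-5)
        assert truth["ECS"] == pytest.approx(y[-1], rel=1e-9)

    def test_dataset_shape_and_determinism(self):
        cfg = simdata.SimConfig(seed=9, n_strains_per_lineage=2, n_replicates=3)
        effects = {("L1", "c"): (4.0, 0.2, 40.0)}
        df1, _ = simdata.simulate_growth_dataset(cfg, effects)
        df2, _ = simdata.simulate_growth_dataset(cfg, effects)
        assert df1.equals(df2)
        assert set(df1["strain"]) == {"L1_1", "L1_2"}
        assert (df1["colony_size"] > 0).all()

    def test_nonpositive_amplitude_rejected(self):
        cfg = simdata.SimConfig(seed=9)
        with pytest.raises(ValueError, match="amplitude"):
            simdata.simulate_growth_dataset(cfg, {("L", "c"): (0.0, 0.2, 40.0)})


class TestCoverageTrack:
    def test_zero_reads_everywhere(self, rng):
        genes = [GeneModel("g1", "c", 1000, 2000, "+")]
        cov, truth = simdata.simulate_coverage_track(genes, {"g1": 0}, 5000, rng=rng)
        assert cov.sum() == 0 and truth["g1"] == 0

    def test_planted_reads_no_jitter_have_exact_mass(self, rng):
        genes = [GeneModel("g1", "c", 1000, 2000, "+")]
        cov, truth = simdata.simulate_coverage_track(
            genes, {"g1": 500}, 5000, rng=rng, footprint=50, jitter_sd=0.0)
        assert cov.sum() == 500 * 50
        assert truth["g1"] == 500

    def test_gene_past_chromosome_end_rejected(self, rng):
        genes = [GeneModel("g1", "c", 1000, 6000, "+")]
        with pytest.raises(ValueError, match="past"):
            simdata.simulate_coverage_track(genes, {"g1": 1}, 5000, rng=rng)


class TestGraphFrequencies:
    def test_zero_edge_lengths_give_root_frequencies_and_zero_f4(self):
        g = m01_graph()
        zero = g.with_params(lengths={e: 0.0 for e in g.edges})
        freqs, truth = simdata.simulate_graph_frequencies(zero, 500, rng=1)
        base = freqs["SpA"].to_numpy()
        for pop in freqs.columns:
            assert np.allclose(freqs[pop].to_numpy(), base)
        assert all(abs(v) < 1e-12 for v in truth.values())

    def test_alpha_one_matches_source_population(self):
        g = m01_graph(alpha_d=1.0)
        # SpD then draws all ancestry from the SpB stem node B1
        wd = g.path_weights("SpD")
        assert wd[("BC", "B1")] == pytest.approx(1.0)
        assert wd.get(("CsM", "Cs1"), 0.0) == 0.0

    def test_empirical_f4_within_three_se_of_truth(self):
        g = m01_graph()
        freqs, truth = simdata.simulate_graph_frequencies(g, 100_000, rng=11)
        n_bad = 0
        for quad, expected in truth.items():
            st = compute_f4(freqs, quad)
            if abs(st.value - expected) > 3 * st.se:
                n_bad += 1
        assert n_bad <= 1  # ~15 quadruples, 3-SE misses should be rare
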