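"""Seeded recovery experiments exercising each pipeline stage end to end.

Each function simulates data with the in-package generators, runs the
matching analysis stage, and scores the result against the generator's
ground truth.  They power the numbered analysis drivers, the acceptance
script and the acceptance test-suite; sizes are parameters so callers can
scale the Monte-Carlo pieces.

All randomness flows through a single integer seed per experiment.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from . import dating, models, painting, popgen, quantseq, rearrange, simdata
from .growth import mann_whitney_u

__all__ = [
    "dating_slope_experiment",
    "dating_young_old_experiment",
    "painting_recovery",
    "blocklength_mwu_power",
    "brute_force_fitch",
    "fitch_vs_bruteforce",
    "planted_topology_ranking",
    "graph_model_recovery",
    "quantseq_recovery",
]


# ---------------------------------------------------------------------------
# divergence dating
# ---------------------------------------------------------------------------

def _five_taxon_newick(t1: float, t_old: float = 0.002, t_deep: float = 0.011,
                       t_out: float = 0.02) -> str:
    return (
        f"(((SpB:{t1},SpD:{t1}):{t_deep - t1},"
        f"(SpC*:{t_old},SpC:{t_old}):{t_deep - t_old}):{t_out - t_deep},"
        f"SpA:{t_out});"
    )


def _region_T1(config: simdata.SimConfig, tree: str, rng) -> float:
    seqs, _lin, _t = simdata.simulate_lineage_sequences(config, tree=tree, rng=rng)
    aln = {k.rsplit("_", 1)[0]: v for k, v in seqs.items()}
    counts = dating.polarize_and_count_patterns(aln, ("SpB", "SpD", "SpC*", "SpC", "SpA"))
    return dating.estimate_times_five_taxon(counts).T1


def dating_slope_experiment(
    seed: int,
    n_regions: int = 200,
    region_length: int = 2000,
    t1_values: tuple[float, ...] = (0.001, 0.002, 0.003, 0.004, 0.005),
) -> dict:
    """Regress mean T1-hat on the true young-split time across settings.

    Clock simulations at several split times; a well-calibrated estimator
    yields a regression slope near 1 (small downward bias from multiple
    hits at larger times).
    """
    rng = np.random.default_rng(seed)
    config = simdata.SimConfig(
        seed=seed, sequence_length=region_length,
        n_strains_per_lineage=1, within_lineage_time=0.0,
    )
    means = []
    for t1 in t1_values:
        tree = _five_taxon_newick(t1)
        vals = [_region_T1(config, tree, rng) for _ in range(n_regions)]
        means.append(float(np.mean(vals)))
    slope, intercept = np.polyfit(t1_values, means, 1)
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "mean_T1": dict(zip(t1_values, means)),
    }


def dating_young_old_experiment(
    seed: int,
    n_seeds: int = 100,
    n_regions: int = 13,
    region_length: int = 5000,
    t_old: float = 0.004,
    young_factor: float = 0.1,
    alpha: float = 0.05,
) -> dict:
    """How often a 10x-younger hybrid is declared significantly younger.

    Per replicate: ``n_regions`` regions for an old hybrid (split t_old)
    and for a young one (split young_factor * t_old), per-region T1, then
    a one-sided Mann-Whitney test (young < old).
    """
    n_sig = 0
    for i in range(n_seeds):
        rng = np.random.default_rng(seed + i)
        config = simdata.SimConfig(
            seed=seed + i, sequence_length=region_length,
            n_strains_per_lineage=1, within_lineage_time=0.0,
        )
        old_tree = _five_taxon_newick(t_old)
        young_tree = _five_taxon_newick(young_factor * t_old)
        t_young = [_region_T1(config, young_tree, rng) for _ in range(n_regions)]
        t_olds = [_region_T1(config, old_tree, rng) for _ in range(n_regions)]
        res = dating.compare_T_between_groups(t_young, t_olds, alternative="less")
        n_sig += res["p"] < alpha
    return {"n_significant": n_sig, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# ancestry painting
# ---------------------------------------------------------------------------

def painting_recovery(
    seed: int,
    n_genomes: int = 10,
    length: int = 500_000,
    parental_divergence_p: float = 0.02,
    donor_fraction: float = 0.5,
    mean_block_length: int = 10_000,
) -> dict:
    """Base-level painting accuracy and donor-fraction recovery on mosaics.

    Two parents at the given raw divergence, ``n_genomes`` mosaic hybrids,
    triplet-scan painting; accuracy counts a base correct only when it is
    assigned to the true donor (unassigned gaps between informative sites
    count against).
    """
    rng = np.random.default_rng(seed)
    # two-taxon clock whose pairwise difference is parental_divergence_p
    t_half = -0.375 * np.log1p(-4 * parental_divergence_p / 3)
    config = simdata.SimConfig(
        seed=seed, sequence_length=length, n_strains_per_lineage=1,
        within_lineage_time=0.0, hybrid_donor_fraction=donor_fraction,
        mean_block_length=mean_block_length,
    )
    seqs, _lin, _t = simdata.simulate_lineage_sequences(
        config, tree=f"(P1:{t_half},P2:{t_half});", rng=rng
    )
    pa, pb = seqs["P1_1"], seqs["P2_1"]
    n_correct = n_total = 0
    true_frac = inf_frac = 0.0
    for _g in range(n_genomes):
        hybrid, truth = simdata.simulate_hybrid_mosaic(
            pa, pb, config, rng=rng, donors=("P1", "P2")
        )
        segs = painting.triplet_window_scan(hybrid, pa, pb, donors=("P1", "P2"))
        merged = painting.merge_segments(segs, max_gap=0)
        true_arr = np.zeros(length, dtype=np.int8)
        for s in truth:
            if s.donor == "P2":
                true_arr[s.start:s.end] = 1
        inf_arr = np.full(length, -1, dtype=np.int8)
        for s in merged:
            inf_arr[s.start:s.end] = 1 if s.donor == "P2" else 0
        n_correct += int(np.count_nonzero(inf_arr == true_arr))
        n_total += length
        true_frac += float(np.mean(true_arr)) / n_genomes
        inf_frac += float(np.mean(inf_arr == 1)) / n_genomes
    return {
        "accuracy": n_correct / n_total,
        "true_donor_fraction": true_frac,
        "inferred_donor_fraction": inf_frac,
        "fraction_error": abs(inf_frac - true_frac),
    }


def blocklength_mwu_power(
    seed: int,
    n_sims: int = 100,
    n_blocks: int = 50,
    median_ratio: float = 2.0,
    alpha: float = 0.05,
) -> dict:
    """Detection rate of a median_ratio block-length difference.

    Per simulation, two groups of ``n_blocks`` exponential block lengths
    whose medians differ by ``median_ratio``; one-sided Mann-Whitney.
    """
    n_sig = 0
    for i in range(n_sims):
        rng = np.random.default_rng(seed + i)
        short = rng.exponential(1.0, n_blocks)
        long = rng.exponential(median_ratio, n_blocks)
        res = mann_whitney_u(short, long, alternative="less")
        n_sig += res.p < alpha
    return {"n_detected": n_sig, "n_sims": n_sims}


# ---------------------------------------------------------------------------
# rearrangement parsimony
# ---------------------------------------------------------------------------

def brute_force_fitch(topology, character: dict[str, int]) -> int:
    """Minimum changes by exhaustive internal labeling (oracle, n small)."""
    internals: list = []

    def collect(node):
        if not isinstance(node, str):
            internals.append(node)
            collect(node[0])
            collect(node[1])

    collect(topology)

    def count(node, labels) -> tuple[int, int]:
        if isinstance(node, str):
            return character[node], 0
        state = labels[id(node)]
        s1, c1 = count(node[0], labels)
        s2, c2 = count(node[1], labels)
        return state, c1 + c2 + (state != s1) + (state != s2)

    best = None
    for assign in itertools.product((0, 1), repeat=len(internals)):
        labels = {id(n): s for n, s in zip(internals, assign)}
        _root_state, changes = count(topology, labels)
        best = changes if best is None else min(best, changes)
    return best


def _random_topology(labels, rng) -> rearrange.Topology:
    trees = [labels[0]]
    for leaf in labels[1:]:
        trees = list(rearrange._insertions(trees[int(rng.integers(len(trees)))], leaf))
    return rearrange.canonicalize(trees[int(rng.integers(len(trees)))])


def fitch_vs_bruteforce(seed: int, n_instances: int = 1000, n_leaves: int = 6) -> dict:
    """Agreement of Fitch with the exhaustive-labeling oracle."""
    rng = np.random.default_rng(seed)
    labels = [f"g{i}" for i in range(n_leaves)]
    n_agree = 0
    for _ in range(n_instances):
        topo = _random_topology(labels, rng)
        char = {lab: int(rng.integers(2)) for lab in labels}
        n_agree += rearrange.fitch_changes(topo, char) == brute_force_fitch(topo, char)
    return {"n_agree": n_agree, "n_instances": n_instances}


def planted_topology_ranking(
    seed: int,
    n_trials: int = 100,
    n_leaves: int = 6,
    n_events: int = 5,
) -> dict:
    """Whether the planted topology is (tied-)first by total parsimony.

    Per trial: a random rooted topology, ``n_events`` disjoint random
    rearrangements on its branches, signed permutations per leaf, event
    detection against a clean reference leaf, ranking over all 945
    topologies.  Also checks the planted tree scores exactly one change
    per event.
    """
    labels = [f"g{i}" for i in range(n_leaves)]
    topologies = rearrange.enumerate_rooted_topologies(labels)
    n_first = n_exact_score = 0
    for i in range(n_trials):
        rng = np.random.default_rng(seed + i)
        while True:
            true_topo = _random_topology(labels, rng)
            # need a leaf hanging off the root to serve as clean reference
            ref = next(
                (c for c in (true_topo[0], true_topo[1]) if isinstance(c, str)), None
            )
            if ref is not None:
                break
        events = simdata.random_rearrangement_events(
            true_topo, n_events, (10, 10, 10), rng, reference=ref
        )
        perms, _truth = simdata.simulate_block_permutations(true_topo, events)
        matrix = rearrange.permutations_to_characters(perms, reference=ref)
        scores = rearrange.rank_topologies(topologies, matrix)
        best_total = scores[0].total_changes
        by_newick = {s.topology: s for s in scores}
        true_score = by_newick[rearrange.to_newick(true_topo)]
        n_first += true_score.total_changes == best_total
        n_exact_score += true_score.total_changes == n_events
    return {"n_first_or_tied": n_first, "n_exact_score": n_exact_score, "n_trials": n_trials}


# ---------------------------------------------------------------------------
# admixture-graph model recovery
# ---------------------------------------------------------------------------

def graph_model_recovery(
    seed: int,
    n_seeds: int = 100,
    n_snps: int = 100_000,
    alpha_d_true: float = 0.5,
    n_restarts: int = 3,
) -> dict:
    """Rank the 15 candidates on data simulated under the M01 graph.

    Reports how often M01 wins, the recovered SpD mixing proportion, and
    the self-consistency fit_fraction of M01 against its own noiseless
    expectations.
    """
    generating = models.m01_graph(alpha_d=alpha_d_true)
    quads = popgen.all_quadruples(models.POPULATIONS)
    candidates = models.candidate_models()
    n_rank1 = 0
    alpha_errors = []
    for i in range(n_seeds):
        freqs, _truth = simdata.simulate_graph_frequencies(
            generating, n_snps, rng=seed * 100_000 + i
        )
        observed = [popgen.compute_f4(freqs, q) for q in quads]
        fits = popgen.rank_models(candidates, observed, n_restarts=n_restarts, rng=seed + i)
        best = fits[0]
        if best.model_id == "M01":
            n_rank1 += 1
            alpha_errors.append(abs(best.params["alphas"]["DM"] - alpha_d_true))
    # noiseless self-consistency: fitted values within 3 SE in every restart
    noiseless = [
        popgen.F4Statistic(q, popgen.expected_f4_from_graph(generating, q), 1e-3, 10)
        for q in quads
    ]
    self_fit = popgen.fit_admixture_graph(noiseless, generating, n_restarts=10, rng=seed)
    return {
        "n_rank1": n_rank1,
        "n_seeds": n_seeds,
        "max_alpha_error": float(max(alpha_errors)) if alpha_errors else float("nan"),
        "mean_alpha_error": float(np.mean(alpha_errors)) if alpha_errors else float("nan"),
        "self_fit_fraction": self_fit.fit_fraction,
        "self_fit_cost": self_fit.cost,
    }


# ---------------------------------------------------------------------------
# 3' tag counting
# ---------------------------------------------------------------------------

def quantseq_recovery(
    seed: int,
    n_genes: int = 500,
    footprint: int = 50,
    jitter_sd: float = 20.0,
    spacing: int = 3000,
) -> dict:
    """Exact planted-count recovery rate over many synthetic genes."""
    rng = np.random.default_rng(seed)
    genes = [
        quantseq.GeneModel(
            f"g{i:04d}", "chrQ", spacing * i + 500, spacing * i + 1500,
            "+" if i % 2 == 0 else "-",
        )
        for i in range(n_genes)
    ]
    # minus-strand genes need their 3' window clear of the previous gene
    genes = [
        g if g.strand == "+" else quantseq.GeneModel(g.gene_id, g.chromosome,
                                                     g.start + 900, g.end + 900, "-")
        for g in genes
    ]
    counts = {g.gene_id: int(rng.integers(20, 500)) for g in genes}
    coverage, truth = simdata.simulate_coverage_track(
        genes, counts, chrom_length=spacing * n_genes + 2000,
        rng=rng, footprint=footprint, jitter_sd=jitter_sd,
    )
    track = quantseq.CoverageTrack("chrQ", coverage)
    table = quantseq.count_genes(track, genes, footprint=footprint)
    recovered = [
        int(round(c)) == truth[g] for g, c in zip(table["gene_id"], table["count"])
    ]
    return {"n_exact": int(np.sum(recovered)), "n_genes": n_genes}
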