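"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the study system: five wild-yeast lineages
diverging under a strict clock with a deep split and two nested
hybridizations of different ages, mosaic hybrid chromosomes with tunable
donor fraction and block length, inversions/translocations planted on a
known topology, replicated logistic colony-growth curves, single-peak 3'
coverage profiles, and allele frequencies drifted along a known admixture
graph.  Every generator records the truth needed to score the matching
pipeline stage, and a fixed seed reproduces byte-identical output.

Units: branch "times" are expected substitutions/site when
``mutation_rate = 1`` (the default), so a deep split of 0.011 per branch
yields ~2.2% pairwise divergence.  Coordinates are 0-based half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .painting import AncestrySegment
from .popgen import AdmixtureGraph, all_quadruples, expected_f4_from_graph
from .rearrange import SignedPermutation, Topology, tree_clades, tree_leaves

__all__ = [
    "SimConfig",
    "TruthSet",
    "RearrangementEvent",
    "default_clock_tree",
    "simulate_lineage_sequences",
    "simulate_hybrid_mosaic",
    "simulate_block_permutations",
    "random_rearrangement_events",
    "simulate_growth_dataset",
    "logistic_true_metrics",
    "simulate_coverage_track",
    "simulate_graph_frequencies",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Knobs shared by the generators; defaults mirror the study setting:
    ~2.2% divergence between the two deep parental lineages, a 50/50
    mosaic hybrid with ~10-kb blocks, and 12 growth replicates."""

    seed: int = 0
    sequence_length: int = 1_000_000
    mutation_rate: float = 1.0  # substitutions/site per unit branch time
    split_times: dict = field(
        default_factory=lambda: {
            "outgroup": 0.02,   # SpA-like outgroup depth, per branch
            "deep": 0.011,      # SpB/SpC-like split (~2.2% pairwise)
            "old_hybrid": 0.002,   # SpC*-like hybridization age
            "young_hybrid": 0.0003,  # SpD-like hybridization age
        }
    )
    n_strains_per_lineage: int = 4
    within_lineage_time: float = 0.0005
    hybrid_donor_fraction: float = 0.5
    mean_block_length: int = 10_000
    growth_noise_sd: float = 0.1  # log2-size units
    n_replicates: int = 12

    def __post_init__(self) -> None:
        if not 0.0 <= self.hybrid_donor_fraction <= 1.0:
            raise ValueError("hybrid_donor_fraction must lie in [0, 1]")
        for name in ("mutation_rate", "mean_block_length", "growth_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthSet:
    """Ground truth emitted by the generators, keyed by pipeline stage."""

    true_segments: list[AncestrySegment] | None = None
    true_event_matrix: pd.DataFrame | None = None
    true_counts: dict[str, int] | None = None
    true_f4: dict[tuple, float] | None = None
    true_T1_T2: dict | None = None
    true_metrics: dict | None = None


# ---------------------------------------------------------------------------
# clock-tree sequence simulation (JC69)
# ---------------------------------------------------------------------------

def default_clock_tree(config: SimConfig) -> str:
    """Five-lineage clock newick matching ``config.split_times``.

    Shape (((SpB, SpD), (SpC*, SpC)), SpA): the young hybrid SpD sits next
    to SpB and the old hybrid SpC* next to SpC, which is the arrangement
    the five-taxon dating estimator assumes for derived-variant patterns.
    """
    s = config.split_times
    t_out, t_deep = s["outgroup"], s["deep"]
    t_old, t_young = s["old_hybrid"], s["young_hybrid"]
    return (
        f"(((SpB:{t_young},SpD:{t_young}):{t_deep - t_young},"
        f"(SpC*:{t_old},SpC:{t_old}):{t_deep - t_old}):{t_out - t_deep},"
        f"SpA:{t_out});"
    )


def _jc69_mutate(seq: np.ndarray, time: float, mu: float, rng) -> np.ndarray:
    """One JC69 step: each site differs with p = (3/4)(1 - exp(-4*mu*t/3)),
    landing uniformly on one of the three other bases.  This is the exact
    JC69 transition kernel, so steps compose along a path."""
    p = 0.75 * (1.0 - math.exp(-4.0 * mu * time / 3.0))
    out = seq.copy()
    hit = rng.random(seq.size) < p
    n = int(hit.sum())
    if n:
        out[hit] = (out[hit] + rng.integers(1, 4, size=n).astype(np.uint8)) % 4
    return out


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def simulate_lineage_sequences(
    config: SimConfig,
    tree: str | dendropy.Tree | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], dict[str, str], dendropy.Tree]:
    """Evolve sequences site-independently under JC69 along a clock tree.

    Returns ``(sequences, lineage_map, tree)`` with
    ``config.n_strains_per_lineage`` strains per leaf lineage, each strain
    diverging from its lineage tip for ``config.within_lineage_time``.
    The expected proportion of differing sites between two strains whose
    paths sum to time t is (3/4)(1 - exp(-4*mu*t/3)).
    """
    if rng is None:
        rng = config.rng()
    if tree is None:
        tree = default_clock_tree(config)
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    for node in tree.preorder_node_iter():
        if len(node.child_nodes()) > 2:
            raise ValueError("polytomies are not supported; provide a binary tree")
        if node.parent_node is not None and (node.edge.length or 0) < 0:
            raise ValueError("branch times must be non-negative")

    L, mu = config.sequence_length, config.mutation_rate
    root_seq = rng.integers(0, 4, size=L, dtype=np.uint8)
    seqs_at: dict = {tree.seed_node: root_seq}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_seq = seqs_at[node.parent_node]
        seqs_at[node] = _jc69_mutate(parent_seq, node.edge.length or 0.0, mu, rng)

    sequences: dict[str, str] = {}
    lineage_map: dict[str, str] = {}
    for leaf in tree.leaf_node_iter():
        lineage = leaf.taxon.label
        tip = seqs_at[leaf]
        for i in range(config.n_strains_per_lineage):
            strain = f"{lineage}_{i + 1}"
            codes = _jc69_mutate(tip, config.within_lineage_time, mu, rng)
            sequences[strain] = _codes_to_str(codes)
            lineage_map[strain] = lineage
    return sequences, lineage_map, tree


# ---------------------------------------------------------------------------
# mosaic hybrid chromosomes
# ---------------------------------------------------------------------------

def simulate_hybrid_mosaic(
    parent_a: str,
    parent_b: str,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    strain: str = "hybrid",
    chromosome: str = "chr",
    donors: tuple[str, str] = ("parentA", "parentB"),
) -> tuple[str, list[AncestrySegment]]:
    """Alternate exponentially-sized donor blocks from two aligned parents.

    The donor-B fraction is ``config.hybrid_donor_fraction`` f and B blocks
    have mean ``config.mean_block_length``; A blocks get mean scaled by
    (1-f)/f so the process is stationary at fraction f.  Truth segments
    tile the chromosome base-exactly.
    """
    if len(parent_a) != len(parent_b):
        raise ValueError("parents must be aligned to equal length")
    if rng is None:
        rng = config.rng()
    L = len(parent_a)
    f = config.hybrid_donor_fraction
    if f in (0.0, 1.0):
        donor = donors[0] if f == 0.0 else donors[1]
        seq = parent_a if f == 0.0 else parent_b
        return seq, [AncestrySegment(strain, chromosome, 0, L, donor)]

    mean_b = float(config.mean_block_length)
    mean_a = mean_b * (1.0 - f) / f
    state = int(rng.random() < f)  # 1 = donor B
    segments: list[AncestrySegment] = []
    a = np.frombuffer(parent_a.encode(), dtype="S1")
    b = np.frombuffer(parent_b.encode(), dtype="S1")
    hybrid = np.empty(L, dtype="S1")
    pos = 0
    while pos < L:
        mean = mean_b if state else mean_a
        length = max(1, int(round(rng.exponential(mean))))
        end = min(L, pos + length)
        hybrid[pos:end] = (b if state else a)[pos:end]
        segments.append(
            AncestrySegment(strain, chromosome, pos, end, donors[state])
        )
        pos = end
        state = 1 - state
    return hybrid.tobytes().decode(), segments


# ---------------------------------------------------------------------------
# planted genome rearrangements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RearrangementEvent:
    """One rearrangement planted on a branch of the true topology.

    ``clade`` is the set of leaves below the branch; ``block_ids`` the
    contiguous run of reference blocks affected; ``dest_chrom`` the target
    chromosome index for translocations.
    """

    kind: str  # "inversion" | "translocation"
    clade: frozenset
    block_ids: tuple[int, ...]
    dest_chrom: int | None = None

    @property
    def key(self) -> tuple[str, tuple[int, ...]]:
        return (self.kind, tuple(sorted(self.block_ids)))


def _apply_event(chromosomes: list[list[int]], event: RearrangementEvent) -> None:
    ids = set(event.block_ids)
    for ci, chrom in enumerate(chromosomes):
        idx = [i for i, b in enumerate(chrom) if abs(b) in ids]
        if not idx:
            continue
        if len(idx) != len(ids) or idx != list(range(idx[0], idx[-1] + 1)):
            raise ValueError(f"event blocks {sorted(ids)} not contiguous in genome")
        lo, hi = idx[0], idx[-1] + 1
        if event.kind == "inversion":
            chrom[lo:hi] = [-b for b in reversed(chrom[lo:hi])]
        elif event.kind == "translocation":
            run = chrom[lo:hi]
            del chrom[lo:hi]
            chromosomes[event.dest_chrom].extend(run)
        else:
            raise ValueError(f"unknown event kind {event.kind!r}")
        return
    raise ValueError(f"blocks {sorted(ids)} not found in genome")


def simulate_block_permutations(
    topology: Topology,
    events: list[RearrangementEvent],
    chrom_sizes: tuple[int, ...] = (10, 10, 10),
) -> tuple[list[SignedPermutation], pd.DataFrame]:
    """Signed block permutations per leaf genome plus the true event matrix.

    The reference arrangement numbers blocks 1..N left to right across
    chromosomes, all positively oriented.  Each leaf genome carries
    exactly the events on its root-to-leaf path (those whose clade
    contains the leaf).  Overlapping inversions on one branch are rejected
    because their truth would be ambiguous.
    """
    leaves = sorted(tree_leaves(topology))
    clades = set(tree_clades(topology))
    for ev in events:
        if ev.clade not in clades:
            raise ValueError(f"event clade {set(ev.clade)} is not a branch of the topology")
        if ev.kind == "translocation" and ev.dest_chrom is None:
            raise ValueError("translocation events need a dest_chrom")
    invs = [e for e in events if e.kind == "inversion"]
    for i, e1 in enumerate(invs):
        for e2 in invs[i + 1 :]:
            if e1.clade == e2.clade and set(e1.block_ids) & set(e2.block_ids):
                raise ValueError("overlapping inversions on one branch are ambiguous")

    next_id = 1
    reference: list[list[int]] = []
    for size in chrom_sizes:
        reference.append(list(range(next_id, next_id + size)))
        next_id += size

    perms = []
    for leaf in leaves:
        chroms = [list(c) for c in reference]
        for ev in events:
            if leaf in ev.clade:
                _apply_event(chroms, ev)
        perms.append(SignedPermutation(leaf, chroms))

    matrix = pd.DataFrame(
        {ev.key: [1 if leaf in ev.clade else 0 for leaf in leaves] for ev in events},
        index=leaves,
        dtype=int,
    )
    return perms, matrix


def random_rearrangement_events(
    topology: Topology,
    n_events: int,
    chrom_sizes: tuple[int, ...],
    rng: np.random.Generator,
    reference: str | None = None,
    max_run: int = 3,
    min_clade_size: int = 1,
) -> list[RearrangementEvent]:
    """Plant ``n_events`` disjoint random events on random branches.

    Branches whose clade contains ``reference`` (or covers all leaves) are
    excluded so that event detection relative to that genome recovers the
    truth matrix with the planted polarity.  ``min_clade_size > 1``
    restricts events to internal branches, whose characters are
    informative about the topology.
    """
    leaves = set(tree_leaves(topology))
    clades = [
        c for c in tree_clades(topology)
        if c != leaves
        and len(c) >= min_clade_size
        and (reference is None or reference not in c)
    ]
    if not clades:
        raise ValueError("no eligible branches for planting events")
    bounds = np.cumsum((0,) + tuple(chrom_sizes))
    used: set[int] = set()
    events: list[RearrangementEvent] = []
    attempts = 0
    while len(events) < n_events:
        attempts += 1
        if attempts > 1000 * n_events:
            raise RuntimeError("could not place disjoint events; fewer/larger chromosomes?")
        ci = int(rng.integers(len(chrom_sizes)))
        lo, hi = int(bounds[ci]) + 1, int(bounds[ci + 1])
        run = int(rng.integers(1, max_run + 1))
        if hi - lo + 1 < run:
            continue
        start = int(rng.integers(lo, hi - run + 2))
        ids = tuple(range(start, start + run))
        # keep a one-block buffer between event runs: id-adjacent runs can
        # fuse into a single rearranged run in a genome carrying both
        # (e.g. two translocations appended to the same chromosome), which
        # would make the planted truth ambiguous
        if used & set(range(start - 1, start + run + 1)):
            continue
        kind = "inversion" if rng.random() < 0.5 else "translocation"
        dest = None
        if kind == "translocation":
            if len(chrom_sizes) < 2:
                continue
            choices = [i for i in range(len(chrom_sizes)) if i != ci]
            dest = int(rng.choice(choices))
        clade = clades[int(rng.integers(len(clades)))]
        ev = RearrangementEvent(kind, clade, ids, dest)
        if any(ev.key == other.key for other in events):
            continue
        used.update(ids)
        events.append(ev)
    return events


# ---------------------------------------------------------------------------
# colony growth curves
# ---------------------------------------------------------------------------

def logistic_true_metrics(
    K: float, r: float, t_mid: float, times: np.ndarray
) -> dict[str, float]:
    """Closed-form AUC/MS/ECS of the noiseless normalized logistic curve
    y(t) = K/(1+exp(-r(t-t_mid))) - y0 over the observed time range."""
    t0, t1 = float(times[0]), float(times[-1])
    f = lambda t: K / (1.0 + math.exp(-r * (t - t_mid)))
    F = lambda t: (K / r) * math.log1p(math.exp(r * (t - t_mid)))
    y0 = f(t0)
    return {
        "AUC": (F(t1) - F(t0)) - y0 * (t1 - t0),
        "MS": r * K / 4.0,
        "ECS": f(t1) - y0,
    }


def simulate_growth_dataset(
    config: SimConfig,
    lineage_effects: dict[tuple[str, str], tuple[float, float, float]],
    times: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    baseline_log2: float = 8.0,
) -> tuple[pd.DataFrame, dict]:
    """Replicated logistic colony-size series with log-additive noise.

    ``lineage_effects`` maps (lineage, condition) -> (K, r, t_mid): the
    log2-size amplitude, growth rate and inflection time of the logistic.
    Returns a long table (strain, lineage, condition, time_h, replicate,
    colony_size, flag) in linear size units and the closed-form true
    metrics per lineage x condition.
    """
    if rng is None:
        rng = config.rng()
    if times is None:
        times = np.arange(0.0, 81.0, 4.0)
    if len(times) < 5:
        raise ValueError("need at least five time points")
    rows = []
    truth = {}
    for (lineage, condition), (K, r, t_mid) in sorted(lineage_effects.items()):
        if K <= 0:
            raise ValueError("logistic amplitude must exceed the initial size")
        truth[(lineage, condition)] = logistic_true_metrics(K, r, t_mid, times)
        log2_curve = baseline_log2 + K / (1.0 + np.exp(-r * (times - t_mid)))
        for i in range(config.n_strains_per_lineage):
            strain = f"{lineage}_{i + 1}"
            for rep in range(config.n_replicates):
                noise = rng.normal(0.0, config.growth_noise_sd, size=len(times))
                sizes = np.power(2.0, log2_curve + noise)
                for t, s in zip(times, sizes):
                    rows.append(
                        {
                            "strain": strain,
                            "lineage": lineage,
                            "condition": condition,
                            "time_h": float(t),
                            "replicate": rep,
                            "colony_size": float(s),
                            "flag": False,
                        }
                    )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# 3' coverage tracks
# ---------------------------------------------------------------------------

def simulate_coverage_track(
    genes,
    counts: dict[str, int],
    chrom_length: int,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
    footprint: int = 50,
    jitter_sd: float = 20.0,
) -> tuple[np.ndarray, dict[str, int]]:
    """Place fixed-width read footprints near each gene's 3' end.

    Read anchors sit so the read abuts the 3' gene boundary, jittered by a
    rounded normal offset and clipped into the chromosome.  Returns the
    per-base coverage array and the planted per-gene counts.
    """
    if rng is None:
        rng = (config or SimConfig()).rng()
    for g in genes:
        if g.end > chrom_length or g.start < 0:
            raise ValueError(f"gene {g.gene_id} extends past the chromosome")
    delta = np.zeros(chrom_length + 1, dtype=np.int64)
    true_counts = {}
    for g in genes:
        n = int(counts.get(g.gene_id, 0))
        true_counts[g.gene_id] = n
        if n == 0:
            continue
        anchor = g.end - footprint if g.strand == "+" else g.start
        jitter = np.round(rng.normal(0.0, jitter_sd, size=n)).astype(int)
        starts = np.clip(anchor + jitter, 0, chrom_length - footprint)
        np.add.at(delta, starts, 1)
        np.add.at(delta, starts + footprint, -1)
    coverage = np.cumsum(delta[:-1])
    return coverage, true_counts


# ---------------------------------------------------------------------------
# allele frequencies on an admixture graph
# ---------------------------------------------------------------------------

def simulate_graph_frequencies(
    graph: AdmixtureGraph,
    n_snps: int,
    rng: np.random.Generator | int | None = None,
    root_range: tuple[float, float] = (0.25, 0.75),
) -> tuple[pd.DataFrame, dict[tuple, float]]:
    """Drift allele frequencies along the graph edges.

    The root frequency is uniform on ``root_range``; each drift edge adds
    an independent normal perturbation with variance equal to the edge
    length (clipped to [0, 1]); an admixture node is the alpha-weighted
    average of its two sources.  Returns population frequencies (one
    column per leaf label) and the path-overlap expected f4 for every
    quadruple orientation.
    """
    rng = np.random.default_rng(rng)
    order = graph.topological_order()
    freqs: dict[str, np.ndarray] = {}
    for node in order:
        links = graph.parent_links(node)
        if not links:
            freqs[node] = rng.uniform(*root_range, size=n_snps)
        elif node in graph.admixture:
            (s1, a1, _), (s2, a2, _) = links
            freqs[node] = a1 * freqs[s1] + a2 * freqs[s2]
        else:
            (parent, _w, edge) = links[0]
            sd = math.sqrt(graph.edges[edge])
            freqs[node] = np.clip(
                freqs[parent] + rng.normal(0.0, sd, size=n_snps), 0.0, 1.0
            )
    table = pd.DataFrame({label: freqs[node] for node, label in graph.leaves.items()})
    quads = all_quadruples(list(graph.leaves.values()))
    true_f4 = {q: expected_f4_from_graph(graph, q) for q in quads}
    return table, true_f4
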