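"""Rearrangement-parsimony ranking of genome topologies.

Collinear-block permutations (GRIMM-style signed block orders) are turned
into binary presence/absence characters — one column per candidate
inversion or translocation event, shared by the genomes carrying the
identical rearranged run — and every rooted bifurcating topology over the
genome labels is scored by Fitch small parsimony on those characters.
Topologies are ranked by the total minimum number of changes; events that
need two or more changes on a topology are reported as conflicting
(homoplastic).  This replaces ancestral signed-permutation reconstruction
(a genome-median problem, NP-hard) with an event-presence surrogate that
still yields per-branch event placements and conflict calls.

Topologies are represented as nested ``(left, right)`` tuples of leaf
labels; the canonical form sorts children by their smallest leaf, and the
canonical newick string is derived from it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CollinearBlock",
    "SignedPermutation",
    "RearrangementCharacterMatrix",
    "TopologyScore",
    "filter_collinear_blocks",
    "permutations_to_characters",
    "enumerate_rooted_topologies",
    "fitch_changes",
    "rank_topologies",
    "canonicalize",
    "to_newick",
    "tree_leaves",
    "tree_clades",
]

Topology = object  # str leaf or (Topology, Topology) tuple


# ---------------------------------------------------------------------------
# collinear blocks and signed permutations
# ---------------------------------------------------------------------------

@dataclass
class CollinearBlock:
    """One locally collinear block; ``occurrences`` maps genome ->
    (chromosome, start, end, orientation) and may omit genomes."""

    block_id: int
    occurrences: dict[str, tuple[str, int, int, str]]

    def length_in(self, genome: str) -> int:
        _c, start, end, _o = self.occurrences[genome]
        if end - start <= 0:
            raise ValueError(f"block {self.block_id} empty in {genome}")
        return end - start


@dataclass
class SignedPermutation:
    genome: str
    chromosomes: list[list[int]]

    def __post_init__(self) -> None:
        ids = [abs(b) for chrom in self.chromosomes for b in chrom]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate block id in genome {self.genome}")
        if 0 in ids:
            raise ValueError("block id 0 is not representable in signed form")


def filter_collinear_blocks(
    blocks: list[CollinearBlock],
    min_length: int = 500,
    require_all: bool = True,
    genomes: list[str] | None = None,
) -> list[CollinearBlock]:
    """Drop blocks shorter than ``min_length`` (strict) in any genome where
    present, and — if ``require_all`` — blocks absent from any genome."""
    if genomes is None:
        genomes = sorted({g for b in blocks for g in b.occurrences})
    kept = []
    for b in blocks:
        if require_all and set(genomes) - set(b.occurrences):
            continue
        if any(b.length_in(g) < min_length for g in b.occurrences):
            continue
        kept.append(b)
    return kept


# ---------------------------------------------------------------------------
# event extraction
# ---------------------------------------------------------------------------

@dataclass
class RearrangementCharacterMatrix:
    """Binary genome x event table; events are (type, block-id tuple)."""

    events: list[tuple[str, tuple[int, ...]]]
    matrix: pd.DataFrame  # genomes x event index, entries 0/1

    def __post_init__(self) -> None:
        vals = self.matrix.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("character matrix must be binary")

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "RearrangementCharacterMatrix":
        """Build from a genomes x events table whose columns are event keys."""
        events = list(table.columns)
        m = table.copy()
        m.columns = range(len(events))
        return cls(events, m)

    def drop_uninformative(self) -> "RearrangementCharacterMatrix":
        vals = self.matrix.to_numpy()
        informative = (vals.sum(axis=0) > 0) & (vals.sum(axis=0) < vals.shape[0])
        if not informative.all():
            dropped = [self.events[i] for i in np.flatnonzero(~informative)]
            warnings.warn(f"dropping uninformative event columns: {dropped}")
        return RearrangementCharacterMatrix(
            [e for e, keep in zip(self.events, informative) if keep],
            self.matrix.loc[:, informative],
        )


def _reference_map(ref: SignedPermutation) -> dict[int, tuple[int, int, int]]:
    table = {}
    for ci, chrom in enumerate(ref.chromosomes):
        for pos, b in enumerate(chrom):
            table[abs(b)] = (ci, pos, 1 if b > 0 else -1)
    return table


def _genome_events(
    perm: SignedPermutation, ref_map: dict[int, tuple[int, int, int]]
) -> set[tuple[str, tuple[int, ...]]]:
    events: set[tuple[str, tuple[int, ...]]] = set()
    for ci, chrom in enumerate(perm.chromosomes):
        annotated = []
        for b in chrom:
            bid = abs(b)
            if bid not in ref_map:
                raise ValueError(f"block {bid} absent from reference genome")
            rc, rp, rs = ref_map[bid]
            rel_sign = (1 if b > 0 else -1) * rs
            annotated.append((bid, rc, rp, rel_sign))
        j = 0
        while j < len(annotated):
            bid, rc, rp, rel = annotated[j]
            if rc != ci:
                # relocated run: ref-consecutive ascending, unflipped
                k = j + 1
                while (
                    k < len(annotated)
                    and annotated[k][1] == rc
                    and annotated[k][2] == annotated[k - 1][2] + 1
                    and annotated[k][3] == 1
                    and rel == 1
                ):
                    k += 1
                ids = tuple(sorted(a[0] for a in annotated[j:k]))
                events.add(("translocation", ids))
                j = k
            elif rel == -1:
                # reversed-and-negated run: ref-consecutive descending
                k = j + 1
                while (
                    k < len(annotated)
                    and annotated[k][1] == ci
                    and annotated[k][3] == -1
                    and annotated[k][2] == annotated[k - 1][2] - 1
                ):
                    k += 1
                ids = tuple(sorted(a[0] for a in annotated[j:k]))
                events.add(("inversion", ids))
                j = k
            else:
                j += 1
    return events


def permutations_to_characters(
    perms: list[SignedPermutation], reference: str
) -> RearrangementCharacterMatrix:
    """Derive candidate inversion/translocation presence characters.

    Relative to the reference genome, each maximal run of blocks that is
    reversed-and-negated is one candidate inversion, and each maximal run
    relocated to a different chromosome one candidate translocation.
    Genomes carrying the identical run share the event column; column
    order is canonical (sorted event keys), so the matrix does not depend
    on input order.
    """
    by_name = {p.genome: p for p in perms}
    if reference not in by_name:
        raise ValueError(f"reference genome {reference!r} not among permutations")
    ref_map = _reference_map(by_name[reference])
    per_genome = {p.genome: _genome_events(p, ref_map) for p in perms}
    events = sorted(set().union(*per_genome.values()))
    genomes = sorted(by_name)
    data = np.array(
        [[1 if e in per_genome[g] else 0 for e in events] for g in genomes],
        dtype=int,
    ).reshape(len(genomes), len(events))
    matrix = pd.DataFrame(data, index=genomes, columns=range(len(events)))
    return RearrangementCharacterMatrix(events, matrix)


# ---------------------------------------------------------------------------
# topology enumeration and Fitch parsimony
# ---------------------------------------------------------------------------

def canonicalize(tree: Topology) -> Topology:
    if isinstance(tree, str):
        return tree
    left, right = (canonicalize(c) for c in tree)
    return (left, right) if min(tree_leaves(left)) < min(tree_leaves(right)) else (right, left)


def tree_leaves(tree: Topology) -> list[str]:
    if isinstance(tree, str):
        return [tree]
    return tree_leaves(tree[0]) + tree_leaves(tree[1])


def tree_clades(tree: Topology) -> list[frozenset[str]]:
    """All clades (leaf sets below each node, root included)."""
    if isinstance(tree, str):
        return [frozenset([tree])]
    out = tree_clades(tree[0]) + tree_clades(tree[1])
    out.append(frozenset(tree_leaves(tree)))
    return out


def to_newick(tree: Topology) -> str:
    def fmt(t):
        return t if isinstance(t, str) else f"({fmt(t[0])},{fmt(t[1])})"

    return fmt(canonicalize(tree)) + ";"


def _insertions(tree: Topology, leaf: str):
    yield (tree, leaf)
    if not isinstance(tree, str):
        left, right = tree
        for t in _insertions(left, leaf):
            yield (t, right)
        for t in _insertions(right, leaf):
            yield (left, t)


def enumerate_rooted_topologies(labels: list[str]) -> list[Topology]:
    """All (2n-3)!! rooted bifurcating topologies over the labels.

    Built by inserting each successive leaf on every edge (including above
    the root) of every partial tree; guarded to n <= 8 against the
    double-factorial blow-up.
    """
    labels = sorted(labels)
    n = len(labels)
    if not 2 <= n <= 8:
        raise ValueError(
            f"topology enumeration supported for 2..8 leaves, got {n} "
            "((2n-3)!! grows too fast beyond that)"
        )
    trees: list[Topology] = [labels[0]]
    for leaf in labels[1:]:
        trees = [t2 for t in trees for t2 in _insertions(t, leaf)]
    return [canonicalize(t) for t in trees]


def fitch_changes(topology: Topology, character: dict[str, int]) -> int:
    """Minimum number of binary state changes on the topology (Fitch)."""

    def walk(node) -> tuple[frozenset[int], int]:
        if isinstance(node, str):
            if node not in character:
                raise ValueError(f"leaf {node!r} has no character state")
            return frozenset([int(character[node])]), 0
        (s1, c1), (s2, c2) = walk(node[0]), walk(node[1])
        inter = s1 & s2
        if inter:
            return inter, c1 + c2
        return s1 | s2, c1 + c2 + 1

    _states, changes = walk(topology)
    return changes


@dataclass
class TopologyScore:
    topology: str  # canonical newick
    total_changes: int
    per_event_changes: dict = field(default_factory=dict)
    conflicting: list = field(default_factory=list)
    rank: int | None = None

    def __post_init__(self) -> None:
        if self.total_changes != sum(self.per_event_changes.values()):
            raise ValueError("total_changes must equal the per-event sum")


def rank_topologies(
    topologies: list[Topology],
    matrix: RearrangementCharacterMatrix,
) -> list[TopologyScore]:
    """Score every topology by total Fitch changes, ascending.

    Uninformative columns are dropped first (with a warning).  Ties share
    the same total; secondary order is the canonical newick string.  On
    each topology the events needing >= 2 changes are reported as
    conflicting.
    """
    matrix = matrix.drop_uninformative()
    if not matrix.events:
        raise ValueError("no informative rearrangement characters to score")
    characters = [
        (event, dict(matrix.matrix.iloc[:, i]))
        for i, event in enumerate(matrix.events)
    ]
    scores = []
    for topo in topologies:
        per_event = {
            event: fitch_changes(topo, char) for event, char in characters
        }
        total = sum(per_event.values())
        scores.append(
            TopologyScore(
                topology=to_newick(topo),
                total_changes=total,
                per_event_changes=per_event,
                conflicting=[e for e, c in per_event.items() if c >= 2],
            )
        )
    scores.sort(key=lambda s: (s.total_changes, s.topology))
    for i, s in enumerate(scores):
        s.rank = i + 1
    return scores
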