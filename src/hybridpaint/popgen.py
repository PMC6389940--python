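"""f4 statistics, admixture graphs, model fitting and JC69 diversity.

The admixture machinery follows the classical drift-covariance view of
f-statistics: populations are leaves of a rooted graph whose edges carry
non-negative drift "lengths" (variances of allele-frequency innovations),
and admixture nodes average two source lineages with proportion ``alpha``.
Under that model

    f4(P1,P2;P3,P4) = E[(p1-p2)(p3-p4)]
                    = sum over drift edges e of (w1(e)-w2(e))*(w3(e)-w4(e))*c_e

where ``wi(e)`` is the fraction of leaf i's ancestry that flows through
edge e (admixture nodes split the flow alpha/(1-alpha)) and ``c_e`` is the
edge length.  This orientation convention (plain products of frequency
differences, pair 1 minus pair 2 times pair 3 minus pair 4) is used
everywhere in the package.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, nnls

__all__ = [
    "GenotypeMatrix",
    "F4Statistic",
    "AdmixtureGraph",
    "ModelFit",
    "filter_variants_min_presence",
    "compute_f4",
    "expected_f4_from_graph",
    "fit_admixture_graph",
    "rank_models",
    "nucleotide_diversity",
    "jc69_from_p",
    "all_quadruples",
]


# ---------------------------------------------------------------------------
# genotype container and presence filter
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Biallelic variant calls for a set of strains.

    Parameters
    ----------
    variants : pandas.DataFrame
        One row per variant with columns ``chromosome, position, ref, alt``;
        positions sorted within chromosome.
    calls : pandas.DataFrame
        Strains (rows) by variants (columns) alternate-allele dosage;
        ``NaN`` marks a missing genotype.
    lineage_map : dict
        Strain name -> lineage label; must cover every strain in ``calls``.
    """

    variants: pd.DataFrame
    calls: pd.DataFrame
    lineage_map: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(self.calls.index) - set(self.lineage_map)
        if missing:
            raise ValueError(f"lineage_map misses strains: {sorted(missing)}")
        if len(self.variants) != self.calls.shape[1]:
            raise ValueError("variants table and calls matrix disagree in size")

    @property
    def lineages(self) -> list[str]:
        return sorted({self.lineage_map[s] for s in self.calls.index})


def filter_variants_min_presence(
    g: GenotypeMatrix,
    min_per_lineage: int = 4,
    require_alt: bool = False,
) -> GenotypeMatrix:
    """Keep variants genotyped in at least ``min_per_lineage`` strains of
    every lineage.

    With ``require_alt=True`` the stricter reading is used: the alternate
    allele itself must be carried by at least ``min_per_lineage`` strains in
    every lineage.  The default (non-missing genotype) retains sites that
    are monomorphic within a lineage, which f4 statistics need.
    """
    strains_by_lineage: dict[str, list[str]] = {}
    for strain in g.calls.index:
        strains_by_lineage.setdefault(g.lineage_map[strain], []).append(strain)
    for lin, strains in strains_by_lineage.items():
        if len(strains) < min_per_lineage:
            raise ValueError(
                f"lineage {lin!r} has only {len(strains)} strains, "
                f"fewer than min_per_lineage={min_per_lineage}"
            )
    keep = np.ones(g.calls.shape[1], dtype=bool)
    for strains in strains_by_lineage.values():
        sub = g.calls.loc[strains]
        if require_alt:
            n_ok = (sub.fillna(0) > 0).sum(axis=0).to_numpy()
        else:
            n_ok = sub.notna().sum(axis=0).to_numpy()
        keep &= n_ok >= min_per_lineage
    return GenotypeMatrix(
        variants=g.variants.loc[keep].reset_index(drop=True),
        calls=g.calls.loc[:, keep],
        lineage_map=dict(g.lineage_map),
    )


# ---------------------------------------------------------------------------
# f4 from allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class F4Statistic:
    quadruple: tuple[str, str, str, str]
    value: float
    se: float
    n_blocks: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError("f4 value must be finite")
        if self.se < 0:
            raise ValueError("standard error must be non-negative")


def compute_f4(
    freqs: pd.DataFrame,
    quadruple: tuple[str, str, str, str],
    block_size: int = 500,
) -> F4Statistic:
    """f4(P1,P2;P3,P4) = mean over SNPs of (p1-p2)(p3-p4).

    ``freqs`` holds one column per population and one row per SNP; the
    standard error is a delete-one block jackknife over contiguous blocks
    of ``block_size`` SNPs.
    """
    for pop in quadruple:
        if pop not in freqs.columns:
            raise ValueError(f"population {pop!r} absent from frequency table")
    p1, p2, p3, p4 = (freqs[pop].to_numpy(float) for pop in quadruple)
    arr = np.stack([p1, p2, p3, p4])
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("allele frequencies must lie in [0, 1]")
    prod = (p1 - p2) * (p3 - p4)
    n = len(prod)
    n_blocks = max(1, n // block_size)
    if n_blocks < 2:
        raise ValueError("need at least two jackknife blocks; lower block_size")
    bounds = np.linspace(0, n, n_blocks + 1).astype(int)
    total = prod.sum()
    value = total / n
    loo = np.empty(n_blocks)
    for i in range(n_blocks):
        lo, hi = bounds[i], bounds[i + 1]
        loo[i] = (total - prod[lo:hi].sum()) / (n - (hi - lo))
    se = math.sqrt((n_blocks - 1) / n_blocks * np.sum((loo - loo.mean()) ** 2))
    return F4Statistic(tuple(quadruple), float(value), float(se), n_blocks)


def all_quadruples(populations: list[str]) -> list[tuple[str, str, str, str]]:
    """All pair-pair splits of 4-subsets, one orientation each."""
    quads = []
    for four in itertools.combinations(sorted(populations), 4):
        a, b, c, d = four
        quads.extend([(a, b, c, d), (a, c, b, d), (a, d, b, c)])
    return quads


# ---------------------------------------------------------------------------
# admixture graphs
# ---------------------------------------------------------------------------

@dataclass
class AdmixtureGraph:
    """Rooted graph of drift edges plus two-parent admixture nodes.

    ``edges`` maps (parent, child) -> drift length (>= 0).  ``admixture``
    maps an admixture node to ``((source1, source2), alpha)`` where alpha is
    the weight on source1; the two mixing edges carry no drift.  ``leaves``
    maps leaf nodes to population labels.
    """

    model_id: str
    edges: dict[tuple[str, str], float]
    admixture: dict[str, tuple[tuple[str, str], float]]
    leaves: dict[str, str]

    def __post_init__(self) -> None:
        for (u, v), length in self.edges.items():
            if length < 0:
                raise ValueError(f"negative drift length on edge {u}->{v}")
        for node, ((s1, s2), alpha) in self.admixture.items():
            if not 0.0 <= alpha <= 1.0:
                raise ValueError(f"alpha for {node} outside [0, 1]")
        parents: dict[str, list[str]] = {}
        for (u, v) in self.edges:
            parents.setdefault(v, []).append(u)
        for v, ps in parents.items():
            if v in self.admixture:
                raise ValueError(f"{v} is both admixture child and drift child")
            if len(ps) > 1:
                raise ValueError(f"non-admixture node {v} has several parents")
        self._toposort()  # raises on cycles

    # -- structure helpers -------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        ns = set(self.leaves)
        for (u, v) in self.edges:
            ns.update((u, v))
        for node, ((s1, s2), _a) in self.admixture.items():
            ns.update((node, s1, s2))
        return ns

    def parent_links(self, node: str) -> list[tuple[str, float, tuple[str, str] | None]]:
        """(parent, ancestry weight, drift edge or None) for one node."""
        if node in self.admixture:
            (s1, s2), alpha = self.admixture[node]
            return [(s1, alpha, None), (s2, 1.0 - alpha, None)]
        links = [(u, 1.0, (u, v)) for (u, v) in self.edges if v == node]
        return links

    def _toposort(self) -> list[str]:
        # sorted traversal keeps the order independent of hash randomization,
        # so simulators drawing random numbers per node are reproducible
        preds: dict[str, set[str]] = {n: set() for n in sorted(self.nodes)}
        for (u, v) in self.edges:
            preds[v].add(u)
        for node, ((s1, s2), _a) in self.admixture.items():
            preds[node].update((s1, s2))
        order, ready = [], sorted(n for n, p in preds.items() if not p)
        preds = {n: set(p) for n, p in preds.items()}
        while ready:
            n = ready.pop(0)
            order.append(n)
            newly = []
            for m, p in preds.items():
                if n in p:
                    p.discard(n)
                    if not p:
                        newly.append(m)
            ready = sorted(set(ready) | set(newly))
        if len(order) != len(preds):
            raise ValueError("admixture graph contains a cycle")
        return order

    def topological_order(self) -> list[str]:
        return self._toposort()

    @property
    def n_admixture(self) -> int:
        return len(self.admixture)

    def path_weights(self, leaf: str) -> dict[tuple[str, str], float]:
        """Ancestry weight of ``leaf`` on every drift edge."""
        weights: dict[tuple[str, str], float] = {}
        stack = [(leaf, 1.0)]
        while stack:
            node, w = stack.pop()
            for parent, share, edge in self.parent_links(node):
                if edge is not None:
                    weights[edge] = weights.get(edge, 0.0) + w * share
                stack.append((parent, w * share))
        return weights

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "edges": [[u, v, l] for (u, v), l in self.edges.items()],
            "admixture": [
                [node, s1, s2, alpha]
                for node, ((s1, s2), alpha) in self.admixture.items()
            ],
            "leaves": dict(self.leaves),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AdmixtureGraph":
        return cls(
            model_id=d["model_id"],
            edges={(u, v): float(l) for u, v, l in d["edges"]},
            admixture={
                node: ((s1, s2), float(alpha))
                for node, s1, s2, alpha in d["admixture"]
            },
            leaves=dict(d["leaves"]),
        )

    def with_params(
        self,
        lengths: dict[tuple[str, str], float] | None = None,
        alphas: dict[str, float] | None = None,
    ) -> "AdmixtureGraph":
        edges = dict(self.edges)
        if lengths:
            edges.update(lengths)
        admixture = dict(self.admixture)
        if alphas:
            for node, a in alphas.items():
                (srcs, _old) = admixture[node]
                admixture[node] = (srcs, a)
        return AdmixtureGraph(self.model_id, edges, admixture, dict(self.leaves))


def expected_f4_from_graph(
    graph: AdmixtureGraph, quadruple: tuple[str, str, str, str]
) -> float:
    """Expected f4 under the drift model (see module docstring)."""
    label_to_node = {lab: node for node, lab in graph.leaves.items()}
    for pop in quadruple:
        if pop not in label_to_node:
            raise ValueError(f"population {pop!r} is not a leaf of the graph")
    w = [graph.path_weights(label_to_node[pop]) for pop in quadruple]
    total = 0.0
    for edge, length in graph.edges.items():
        c1 = w[0].get(edge, 0.0) - w[1].get(edge, 0.0)
        c2 = w[2].get(edge, 0.0) - w[3].get(edge, 0.0)
        total += c1 * c2 * length
    return total


# ---------------------------------------------------------------------------
# least-squares graph fitting and model ranking
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    model_id: str
    params: dict
    cost: float
    fit_fraction: float
    rank: int | None = None
    graph: AdmixtureGraph | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ValueError("cost must be non-negative")
        if not 0.0 <= self.fit_fraction <= 1.0:
            raise ValueError("fit_fraction must lie in [0, 1]")


def _design_matrix(
    graph: AdmixtureGraph,
    quadruples: list[tuple[str, str, str, str]],
    edge_order: list[tuple[str, str]],
) -> np.ndarray:
    label_to_node = {lab: node for node, lab in graph.leaves.items()}
    rows = []
    for quad in quadruples:
        w = [graph.path_weights(label_to_node[pop]) for pop in quad]
        rows.append(
            [
                (w[0].get(e, 0.0) - w[1].get(e, 0.0))
                * (w[2].get(e, 0.0) - w[3].get(e, 0.0))
                for e in edge_order
            ]
        )
    return np.asarray(rows)


def fit_admixture_graph(
    observed: list[F4Statistic],
    graph: AdmixtureGraph,
    n_restarts: int = 10,
    rng: np.random.Generator | int | None = None,
) -> ModelFit:
    """Fit edge lengths (>= 0) and admixture proportions to observed f4.

    The cost is the sum of squared standardized residuals
    ``((expected - observed)/se)**2``.  For fixed admixture proportions the
    expectations are linear in the edge lengths, so each evaluation solves a
    non-negative least-squares problem; the (at most few) alphas are then
    optimized by bounded local search from ``n_restarts`` random starts.
    ``fit_fraction`` is the share of restarts whose optimum leaves every
    residual within 3 standard errors of the observation.
    """
    if not observed:
        raise ValueError("need at least one observed f4 statistic")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    ses = np.array([o.se for o in observed])
    if np.all(ses == 0):
        raise ValueError("all standard errors are zero; weighted cost undefined")
    if np.any(ses <= 0):
        raise ValueError("every observed statistic needs a positive SE")
    rng = np.random.default_rng(rng)

    quadruples = [o.quadruple for o in observed]
    values = np.array([o.value for o in observed])
    weights = 1.0 / ses
    edge_order = list(graph.edges)
    admix_nodes = sorted(graph.admixture)

    def solve(alphas: np.ndarray):
        g = graph.with_params(alphas=dict(zip(admix_nodes, alphas)))
        design = _design_matrix(g, quadruples, edge_order)
        lengths, _res = nnls(design * weights[:, None], values * weights)
        resid = (design @ lengths - values) * weights
        return float(resid @ resid), lengths, design

    best = None
    n_within = 0
    for _ in range(n_restarts):
        if admix_nodes:
            a0 = rng.uniform(0.0, 1.0, size=len(admix_nodes))
            opt = minimize(
                lambda a: solve(a)[0],
                a0,
                method="L-BFGS-B",
                bounds=[(0.0, 1.0)] * len(admix_nodes),
            )
            alphas = opt.x
        else:
            alphas = np.empty(0)
        cost, lengths, design = solve(alphas)
        resid_raw = design @ lengths - values
        if np.all(np.abs(resid_raw) <= 3.0 * ses):
            n_within += 1
        if best is None or cost < best[0]:
            best = (cost, lengths, alphas)

    cost, lengths, alphas = best
    params = {
        "edge_lengths": {f"{u}->{v}": float(l) for (u, v), l in zip(edge_order, lengths)},
        "alphas": {node: float(a) for node, a in zip(admix_nodes, alphas)},
    }
    fitted = graph.with_params(
        lengths=dict(zip(edge_order, lengths)),
        alphas=dict(zip(admix_nodes, alphas)),
    )
    return ModelFit(
        model_id=graph.model_id,
        params=params,
        cost=cost,
        fit_fraction=n_within / n_restarts,
        graph=fitted,
    )


def rank_models(
    models: list[AdmixtureGraph],
    observed: list[F4Statistic],
    n_restarts: int = 10,
    rng: np.random.Generator | int | None = None,
) -> list[ModelFit]:
    """Fit every candidate graph and sort ascending by cost.

    Ties are broken by fewer admixture events, then by model identifier,
    so the ranking does not depend on the input order of the candidates.
    """
    if len(models) < 2:
        raise ValueError("need at least two candidate models to rank")
    rng = np.random.default_rng(rng)
    fits = []
    for graph in sorted(models, key=lambda g: g.model_id):
        fit = fit_admixture_graph(observed, graph, n_restarts=n_restarts, rng=rng)
        fits.append((fit, graph.n_admixture))
    fits.sort(key=lambda t: (t[0].cost, t[1], t[0].model_id))
    out = []
    for rank, (fit, _na) in enumerate(fits, start=1):
        fit.rank = rank
        out.append(fit)
    return out


# ---------------------------------------------------------------------------
# JC69 nucleotide diversity
# ---------------------------------------------------------------------------

_ACGT = np.frombuffer(b"ACGT", dtype="S1")


def jc69_from_p(p: float) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3) for 0 <= p < 0.75."""
    if not 0.0 <= p < 0.75:
        raise ValueError(f"proportion of differing sites {p} is saturated (>= 0.75)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _pairwise_jc69(a: np.ndarray, b: np.ndarray) -> float:
    valid = np.isin(a, _ACGT) & np.isin(b, _ACGT)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no jointly valid sites between sequences")
    p = float(np.count_nonzero(a[valid] != b[valid])) / n
    return jc69_from_p(p)


def nucleotide_diversity(
    sequences: dict[str, str],
    groups: dict[str, list[str]],
) -> tuple[dict[str, float], dict[tuple[str, str], float]]:
    """Mean pairwise JC69 distance within and between lineage groups.

    Sites with a non-ACGT character in either member of a pair are excluded
    pairwise.  Returns ``(within_pi, between_divergence)``; a group of size
    one gets ``within_pi = nan`` (undefined, flagged rather than raised).
    """
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) > 1:
        raise ValueError("sequences must be aligned to equal length")
    arrays = {
        name: np.frombuffer(seq.upper().encode(), dtype="S1")
        for name, seq in sequences.items()
    }
    within: dict[str, float] = {}
    for gname, members in groups.items():
        pairs = list(itertools.combinations(members, 2))
        if not pairs:
            within[gname] = float("nan")
            continue
        within[gname] = float(
            np.mean([_pairwise_jc69(arrays[x], arrays[y]) for x, y in pairs])
        )
    between: dict[tuple[str, str], float] = {}
    for ga, gb in itertools.combinations(sorted(groups), 2):
        dists = [
            _pairwise_jc69(arrays[x], arrays[y])
            for x in groups[ga]
            for y in groups[gb]
        ]
        between[(ga, gb)] = float(np.mean(dists))
    return within, between
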