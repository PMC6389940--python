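"""Site-pattern divergence dating for admixed lineages.

Region alignments are polarized against an outgroup (the last taxon):
the allele matching the outgroup is ancestral "A", the other allele
derived "B", giving per-site patterns such as ``BAAAA``.  Relative
divergence times follow from private-derived-variant counts:

five taxa, topology (((P1, P2), (P3, P4)), Out)::

    T1 = (1/N) * (BAAAA + ABAAA) / 2
    T2 = (1/N) * [ (BAAAA + ABAAA)/2 + BBAAA + (AABAA + AAABA)/2 + AABBA ] / 2

four taxa, topology (((P1, P2), P3), Out)::

    T1 = (1/N) * (BAAA + ABAA) / 2
    T2 = (1/N) * [ (BAAA + ABAA)/2 + BBAA + AABA ] / 2

T1 averages the two private-derived branches of the most recent split;
T2 additionally averages the sister-clade contributions one split deeper.
N defaults to the number of retained alignment columns (sites without
missing data and with at most two alleles), so T is a per-site divergence;
``denominator="informative"`` divides by the polarized variable sites
instead.  The four-taxon weights extend the five-taxon branch-averaging
logic and are an interpretation, not a printed formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .growth import mann_whitney_u

__all__ = [
    "SitePatternCounts",
    "DivergenceEstimate",
    "polarize_and_count_patterns",
    "estimate_times_five_taxon",
    "estimate_times_four_taxon",
    "filter_regions_min_informative",
    "compare_T_between_groups",
    "calibrate_to_years",
]

_VALID = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SitePatternCounts:
    """Polarized derived-variant pattern tallies for one region.

    ``n_sites`` counts all retained alignment columns; ``counts`` maps
    pattern strings (outgroup position always 'A') to tallies over the
    polarized variable sites.
    """

    region: tuple[str, int, int]
    taxa_order: tuple[str, ...]
    n_sites: int
    counts: dict[str, int]

    def __post_init__(self) -> None:
        k = len(self.taxa_order)
        for pat in self.counts:
            if len(pat) != k:
                raise ValueError(f"pattern {pat!r} does not match {k} taxa")
            if pat[-1] != "A":
                raise ValueError("outgroup position must be ancestral 'A'")

    @property
    def n_informative(self) -> int:
        """Number of polarized biallelic variable sites."""
        return sum(self.counts.values())

    def get(self, pattern: str) -> int:
        return self.counts.get(pattern, 0)


@dataclass
class DivergenceEstimate:
    region: tuple[str, int, int]
    strain: str
    T1: float
    T2: float

    def __post_init__(self) -> None:
        if self.T1 < 0 or self.T2 < 0:
            raise ValueError("divergence times must be non-negative")


def polarize_and_count_patterns(
    alignment: dict[str, str],
    taxa_order: tuple[str, ...],
    region: tuple[str, int, int] = ("region", 0, 0),
) -> SitePatternCounts:
    """Tally ancestral/derived site patterns with the outgroup last.

    Columns with a non-ACGT character in any taxon, or with more than two
    alleles, are excluded entirely.  Retained invariant columns contribute
    to ``n_sites`` only.
    """
    if len(taxa_order) < 4:
        raise ValueError("need at least three ingroup taxa plus the outgroup")
    seqs = [alignment[t] for t in taxa_order]
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("sequences must be aligned to equal length")
    mat = np.stack([np.frombuffer(s.upper().encode(), dtype="S1") for s in seqs])
    valid = np.all(np.isin(mat, _VALID), axis=0)
    mat = mat[:, valid]

    # biallelic mask: at most two distinct states per column
    sorted_cols = np.sort(mat, axis=0)
    n_alleles = 1 + np.count_nonzero(sorted_cols[1:] != sorted_cols[:-1], axis=0)
    mat = mat[:, n_alleles <= 2]
    n_sites = mat.shape[1]

    out = mat[-1]
    derived = mat != out  # boolean matrix, outgroup row all False
    variable = derived[:-1].any(axis=0)
    counts: dict[str, int] = {}
    if variable.any():
        sub = derived[:, variable]
        codes = np.where(sub, "B", "A")
        patterns, tallies = np.unique(
            np.apply_along_axis("".join, 0, codes), return_counts=True
        )
        counts = {p: int(c) for p, c in zip(patterns, tallies)}
    return SitePatternCounts(region, tuple(taxa_order), int(n_sites), counts)


def _denominator(c: SitePatternCounts, denominator: str) -> float:
    if denominator == "sites":
        n = c.n_sites
    elif denominator == "informative":
        n = c.n_informative
    else:
        raise ValueError("denominator must be 'sites' or 'informative'")
    if n == 0:
        raise ValueError("N = 0: divergence time undefined for this region")
    return float(n)


def estimate_times_five_taxon(
    c: SitePatternCounts,
    strain: str | None = None,
    denominator: str = "sites",
) -> DivergenceEstimate:
    """T1/T2 for five taxa ordered (P1, P2, P3, P4, outgroup) on the
    topology (((P1, P2), (P3, P4)), Out)."""
    if len(c.taxa_order) != 5:
        raise ValueError("five-taxon estimator needs exactly five taxa")
    n = _denominator(c, denominator)
    t1 = (c.get("BAAAA") + c.get("ABAAA")) / 2.0 / n
    t2 = (
        (c.get("BAAAA") + c.get("ABAAA")) / 2.0
        + c.get("BBAAA")
        + (c.get("AABAA") + c.get("AAABA")) / 2.0
        + c.get("AABBA")
    ) / 2.0 / n
    return DivergenceEstimate(c.region, strain or c.taxa_order[1], t1, t2)


def estimate_times_four_taxon(
    c: SitePatternCounts,
    strain: str | None = None,
    denominator: str = "sites",
) -> DivergenceEstimate:
    """T1/T2 for four taxa ordered (P1, P2, P3, outgroup) on the topology
    (((P1, P2), P3), Out)."""
    if len(c.taxa_order) != 4:
        raise ValueError("four-taxon estimator needs exactly four taxa")
    n = _denominator(c, denominator)
    t1 = (c.get("BAAA") + c.get("ABAA")) / 2.0 / n
    t2 = ((c.get("BAAA") + c.get("ABAA")) / 2.0 + c.get("BBAA") + c.get("AABA")) / 2.0 / n
    return DivergenceEstimate(c.region, strain or c.taxa_order[1], t1, t2)


def filter_regions_min_informative(
    regions: list[SitePatternCounts], min_sites: int = 1000
) -> list[SitePatternCounts]:
    """Keep regions with at least ``min_sites`` informative (variable) sites."""
    return [c for c in regions if c.n_informative >= min_sites]


def compare_T_between_groups(
    estimates_a: list[float],
    estimates_b: list[float],
    alternative: str = "two_sided",
) -> dict:
    """Mann-Whitney comparison of divergence-time estimates between groups."""
    if not estimates_a or not estimates_b:
        raise ValueError("both groups must be non-empty")
    a = np.asarray(estimates_a, dtype=float)
    b = np.asarray(estimates_b, dtype=float)
    res = mann_whitney_u(a, b, alternative=alternative)
    return {
        "U": res.U,
        "p": res.p,
        "method": res.method,
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
    }


def calibrate_to_years(
    t: float,
    substitution_rate: float = 1.67e-10,
    generations_per_year: float = 1.0,
) -> float:
    """Linear rescaling of a per-site divergence into years."""
    return t / (substitution_rate * generations_per_year)
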