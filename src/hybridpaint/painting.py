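"""Ancestry painting of admixed genomes.

Donor-lineage assignment along a hybrid chromosome uses two complementary
criteria: a per-gene fixation rule (every focal strain closer, by JC69
distance, to all donor-panel strains than to any recipient-panel strain)
and a parent-parent-hybrid triplet scan over informative sites.  Segments
are merged across small gaps, summarized as genome-wide donor proportions,
and complemented by per-window heterozygosity/coverage profiles and a
translocation-junction coverage test.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .popgen import jc69_from_p

__all__ = [
    "SequenceAlignment",
    "AncestrySegment",
    "jc69_distance",
    "classify_gene_ancestry",
    "triplet_window_scan",
    "merge_segments",
    "ancestry_proportions",
    "heterozygous_window_profile",
    "junction_translocation_support",
]

_VALID = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SequenceAlignment:
    """Equal-length sequences over {A,C,G,T,N,-} for one chromosome."""

    chromosome: str
    strains: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.strains) != len(self.sequences):
            raise ValueError("one sequence per strain required")
        if len(set(self.strains)) != len(self.strains):
            raise ValueError("strain names must be unique")
        if len({len(s) for s in self.sequences}) > 1:
            raise ValueError("sequences must have equal length")

    def __getitem__(self, strain: str) -> str:
        return self.sequences[self.strains.index(strain)]

    @property
    def length(self) -> int:
        return len(self.sequences[0])


@dataclass(frozen=True)
class AncestrySegment:
    strain: str
    chromosome: str
    start: int
    end: int
    donor: str
    support: float = 1.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty segment [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def jc69_distance(p: float) -> float:
    """JC69 substitutions/site from a proportion of differing sites."""
    return jc69_from_p(p)


def _to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype="S1")


def _pair_distance(a: np.ndarray, b: np.ndarray) -> float:
    """JC69 distance with pairwise exclusion of non-ACGT sites."""
    valid = np.isin(a, _VALID) & np.isin(b, _VALID)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no valid sites shared by the pair")
    return jc69_from_p(float(np.count_nonzero(a[valid] != b[valid])) / n)


def classify_gene_ancestry(
    gene_alignment: SequenceAlignment,
    focal: list[str],
    donor_panel: list[str],
    recipient_panel: list[str],
) -> str:
    """Label one gene {fixed_introgressed, not_introgressed, ambiguous}.

    ``fixed_introgressed``: every focal strain's largest distance to the
    donor panel is strictly smaller than its smallest distance to the
    recipient panel; ``not_introgressed`` is the symmetric condition toward
    the recipients.  Ties, mixed strains, or saturated distances yield
    ``ambiguous``.
    """
    if not focal or not donor_panel or not recipient_panel:
        raise ValueError("focal set and both panels must be non-empty")
    if set(donor_panel) & set(recipient_panel):
        raise ValueError("donor and recipient panels must be disjoint")
    arrays = {s: _to_array(gene_alignment[s]) for s in (*focal, *donor_panel, *recipient_panel)}
    closer_donor = closer_recipient = True
    for f in focal:
        try:
            d_donor = [_pair_distance(arrays[f], arrays[d]) for d in donor_panel]
            d_recip = [_pair_distance(arrays[f], arrays[r]) for r in recipient_panel]
        except ValueError:  # saturated or no shared sites: flag the gene
            return "ambiguous"
        if not max(d_donor) < min(d_recip):
            closer_donor = False
        if not max(d_recip) < min(d_donor):
            closer_recipient = False
    if closer_donor:
        return "fixed_introgressed"
    if closer_recipient:
        return "not_introgressed"
    return "ambiguous"


def triplet_window_scan(
    focal: str,
    parent1: str,
    parent2: str,
    strain: str = "focal",
    chromosome: str = "chr",
    donors: tuple[str, str] = ("parent1", "parent2"),
    max_opposing: int = 0,
) -> list[AncestrySegment]:
    """Paint a focal sequence against two parental sequences.

    Informative sites are positions where the parents differ (both valid)
    and the focal matches exactly one of them.  Maximal runs of sites
    supporting the same parent become segments whose bounds snap to the
    outermost supporting informative site (half-open end).  ``max_opposing``
    allows short interruptions: internal runs of at most that many
    opposing sites are absorbed when flanked by the same donor.
    """
    if not len(focal) == len(parent1) == len(parent2):
        raise ValueError("focal and parents must be aligned to equal length")
    f, p1, p2 = _to_array(focal), _to_array(parent1), _to_array(parent2)
    valid = np.isin(f, _VALID) & np.isin(p1, _VALID) & np.isin(p2, _VALID)
    diff = (p1 != p2) & valid
    m1 = diff & (f == p1)
    m2 = diff & (f == p2)
    pos = np.flatnonzero(m1 | m2)
    if pos.size == 0:
        return []
    which = np.where(m1[pos], 0, 1)

    # maximal same-parent runs
    breaks = np.flatnonzero(np.diff(which)) + 1
    run_bounds = np.concatenate([[0], breaks, [pos.size]])
    runs = [
        (which[run_bounds[i]], run_bounds[i], run_bounds[i + 1])
        for i in range(len(run_bounds) - 1)
    ]
    if max_opposing > 0:
        merged = True
        while merged:
            merged = False
            for i in range(1, len(runs) - 1):
                d_prev, d_mid, d_next = runs[i - 1][0], runs[i][0], runs[i + 1][0]
                n_mid = runs[i][2] - runs[i][1]
                if d_prev == d_next != d_mid and n_mid <= max_opposing:
                    runs[i - 1 : i + 2] = [(d_prev, runs[i - 1][1], runs[i + 1][2])]
                    merged = True
                    break

    segments = []
    for donor_idx, lo, hi in runs:
        sites = pos[lo:hi]
        support_mask = which[lo:hi] == donor_idx
        segments.append(
            AncestrySegment(
                strain=strain,
                chromosome=chromosome,
                start=int(sites[0]),
                end=int(sites[-1]) + 1,
                donor=donors[donor_idx],
                support=float(np.mean(support_mask)),
            )
        )
    return segments


def merge_segments(
    segments: list[AncestrySegment], max_gap: int = 5000
) -> list[AncestrySegment]:
    """Concatenate same-donor neighbours separated by <= ``max_gap`` bases.

    Fragments of shared ancestry within the gap distance are fused
    (inclusive boundary); segments of differing donors are never fused.
    Idempotent.  Overlapping same-strain segments with different donors are
    rejected.
    """
    out: list[AncestrySegment] = []
    keyfn = lambda s: (s.strain, s.chromosome, s.start, s.end)
    for seg in sorted(segments, key=keyfn):
        prev = out[-1] if out else None
        if (
            prev is not None
            and (seg.strain, seg.chromosome) == (prev.strain, prev.chromosome)
            and seg.start < prev.end
            and seg.donor != prev.donor
        ):
            raise ValueError(
                f"overlapping segments with different donors at "
                f"{seg.chromosome}:{seg.start}"
            )
        if (
            prev is not None
            and (seg.strain, seg.chromosome, seg.donor)
            == (prev.strain, prev.chromosome, prev.donor)
            and seg.start - prev.end <= max_gap
        ):
            total = prev.length + seg.length
            support = (prev.support * prev.length + seg.support * seg.length) / total
            out[-1] = replace(prev, end=max(prev.end, seg.end), support=support)
        else:
            out.append(seg)
    return out


def ancestry_proportions(
    segments: list[AncestrySegment], genome_length: int
) -> dict[str, float]:
    """Donor -> genome fraction; the remainder is reported as 'unassigned'."""
    totals: dict[str, int] = {}
    prev_end: dict[tuple[str, str], int] = {}
    for seg in sorted(segments, key=lambda s: (s.strain, s.chromosome, s.start)):
        if seg.end > genome_length:
            raise ValueError(f"segment end {seg.end} beyond genome length {genome_length}")
        key = (seg.strain, seg.chromosome)
        if seg.start < prev_end.get(key, 0):
            raise ValueError("segments must be merged and non-overlapping")
        prev_end[key] = seg.end
        totals[seg.donor] = totals.get(seg.donor, 0) + seg.length
    n_strains = max(1, len({s.strain for s in segments}))
    fractions = {d: t / (genome_length * n_strains) for d, t in totals.items()}
    fractions["unassigned"] = 1.0 - sum(fractions.values())
    return fractions


def heterozygous_window_profile(
    het_positions: np.ndarray | list[int],
    coverage: np.ndarray,
    window: int = 1000,
    chromosome: str = "chr",
) -> pd.DataFrame:
    """Per-window heterozygous-site frequency and mean coverage.

    Tiling windows of ``window`` bases; ``het_site_frequency`` is the count
    of heterozygous calls in the window divided by the window size.
    """
    if window <= 0:
        raise ValueError("window size must be positive")
    coverage = np.asarray(coverage, dtype=float)
    n = len(coverage)
    het = np.zeros(n)
    idx = np.asarray(het_positions, dtype=int)
    if idx.size:
        if idx.min() < 0 or idx.max() >= n:
            raise ValueError("heterozygous position outside coverage track")
        np.add.at(het, idx, 1)
    starts = np.arange(0, n, window)
    rows = []
    for s in starts:
        e = min(s + window, n)
        rows.append(
            {
                "chromosome": chromosome,
                "window_start": int(s),
                "window_size": window,
                "mean_coverage": float(coverage[s:e].mean()),
                "het_site_frequency": float(het[s:e].sum()) / window,
            }
        )
    return pd.DataFrame(rows)


def junction_translocation_support(
    coverage: np.ndarray,
    junction: tuple[int, int],
    min_mean_coverage: float = 5.0,
    max_zero_run: int = 100,
) -> tuple[bool, dict]:
    """Test whether reads support a fusion junction on a scaffold.

    Supported iff mean coverage over the junction interval is at least
    ``min_mean_coverage`` and the junction contains no zero-coverage run of
    ``max_zero_run`` bases or longer.
    """
    coverage = np.asarray(coverage, dtype=float)
    if coverage.size == 0:
        raise ValueError("empty coverage track")
    start, end = junction
    if not (0 <= start < end <= coverage.size):
        raise ValueError("junction interval outside scaffold")
    region = coverage[start:end]
    mean_cov = float(region.mean())
    longest_zero = run = 0
    for v in region:
        run = run + 1 if v == 0 else 0
        longest_zero = max(longest_zero, run)
    supported = mean_cov >= min_mean_coverage and longest_zero < max_zero_run
    stats = {
        "mean_coverage": mean_cov,
        "longest_zero_run": longest_zero,
        "junction_length": end - start,
    }
    return supported, stats
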