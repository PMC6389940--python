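"""Readers and writers for the pipeline's file formats.

FASTA via Biopython; BED/TSV via pandas; GRIMM signed-permutation text by
hand (the dialect is too small for a library: ``>name`` headers, signed
integer block ids, ``$`` chromosome terminators).  Coordinates are
0-based half-open everywhere.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .painting import AncestrySegment
from .rearrange import SignedPermutation

__all__ = [
    "read_fasta",
    "write_fasta",
    "segments_to_bed",
    "bed_to_segments",
    "parse_grimm",
    "write_grimm",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA record {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def segments_to_bed(segments: list[AncestrySegment], path: str | Path) -> None:
    """BED with name = donor and extra strain/support columns."""
    df = pd.DataFrame(
        {
            "chrom": [s.chromosome for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "name": [s.donor for s in segments],
            "score": [round(s.support * 1000) for s in segments],
            "strain": [s.strain for s in segments],
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def bed_to_segments(path: str | Path) -> list[AncestrySegment]:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strain"],
    )
    return [
        AncestrySegment(
            strain=str(r.strain),
            chromosome=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            donor=str(r.name),
            support=float(r.score) / 1000.0,
        )
        for r in df.itertuples()
    ]


def parse_grimm(text: str) -> list[SignedPermutation]:
    """Parse GRIMM text: '>genome' headers, signed ids, '$'-ended chromosomes."""
    perms: list[SignedPermutation] = []
    name: str | None = None
    chromosomes: list[list[int]] = []
    current: list[int] = []
    seen: set[int] = set()

    def flush() -> None:
        nonlocal chromosomes, current, seen
        if name is not None:
            if current:
                raise ValueError(f"genome {name!r}: last chromosome missing '$'")
            perms.append(SignedPermutation(name, chromosomes))
        chromosomes, current, seen = [], [], set()

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].strip()
            if not name:
                raise ValueError(f"line {lineno}: empty genome name")
            continue
        if name is None:
            raise ValueError(f"line {lineno}: data before any '>' header")
        for tok in line.split():
            if tok == "$":
                chromosomes.append(current)
                current = []
                continue
            try:
                b = int(tok)
            except ValueError:
                raise ValueError(f"line {lineno}: bad token {tok!r}") from None
            if abs(b) in seen:
                raise ValueError(
                    f"line {lineno}: duplicate block id {abs(b)} in genome {name!r}"
                )
            seen.add(abs(b))
            current.append(b)
    flush()
    return perms


def write_grimm(perms: list[SignedPermutation]) -> str:
    lines = []
    for p in perms:
        lines.append(f">{p.genome}")
        for chrom in p.chromosomes:
            lines.append(" ".join(str(b) for b in chrom) + " $")
    return "\n".join(lines) + "\n"
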