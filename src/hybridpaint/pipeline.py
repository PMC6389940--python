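"""End-to-end synthetic pipeline orchestration.

``run_pipeline`` chains the stages (simulate -> paint / date / rearrange /
f4 / growth / quantseq) on in-package synthetic data, writes one TSV per
stage plus a JSON run manifest (effective config, seed, per-stage row
counts, output checksums).  Deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dating, growth, models, painting, popgen, quantseq, rearrange, simdata
from .io import segments_to_bed, write_fasta, write_grimm

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "DEFAULT_PARAMS"]

# stage parameters default to the study's filter settings
DEFAULT_PARAMS = {
    "merge_gap": 5000,
    "min_informative_sites": 1000,
    "min_block_length": 500,
    "min_strains_per_lineage": 4,
    "initial_window_inside": 100,
    "initial_window_downstream": 300,
    "slope_window": 5,
    "r_min": 0.8,
    "slope_percentile": 98,
    "sequence_length": 200_000,
    "n_snps": 20_000,
    "n_genes": 50,
    "n_topology_leaves": 6,
}

ALL_STAGES = ("paint", "date", "rearrange", "f4", "growth", "quantseq")


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str | Path = "pipeline_out"
    stages: tuple[str, ...] = ALL_STAGES
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.params) - set(DEFAULT_PARAMS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        self.effective = {**DEFAULT_PARAMS, **self.params}


@dataclass
class RunManifest:
    seed: int
    config: dict
    row_counts: dict
    checksums: dict
    started: float
    finished: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "config": self.config,
                "row_counts": self.row_counts,
                "checksums": self.checksums,
                "started": self.started,
                "finished": self.finished,
            },
            indent=1,
            default=str,
        )


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    started = time.time()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    p = config.effective
    row_counts: dict[str, int] = {}

    sim = simdata.SimConfig(
        seed=config.seed,
        sequence_length=p["sequence_length"],
        n_strains_per_lineage=1,
    )
    rng = sim.rng()

    if "paint" in config.stages:
        seqs, _lin, _tree = simdata.simulate_lineage_sequences(sim, rng=rng)
        pa, pb = seqs["SpB_1"], seqs["SpC_1"]
        hybrid, truth = simdata.simulate_hybrid_mosaic(
            pa, pb, sim, rng=rng, strain="hybrid", donors=("SpB", "SpC")
        )
        write_fasta({"SpB": pa, "SpC": pb, "hybrid": hybrid}, out / "paint_input.fasta")
        segs = painting.triplet_window_scan(
            hybrid, pa, pb, strain="hybrid", donors=("SpB", "SpC")
        )
        merged = painting.merge_segments(segs, max_gap=p["merge_gap"])
        segments_to_bed(merged, out / "paint_segments.bed")
        props = painting.ancestry_proportions(merged, len(hybrid))
        pd.DataFrame([props]).to_csv(out / "paint_proportions.tsv", sep="\t", index=False)
        row_counts["paint"] = len(merged)

    if "date" in config.stages:
        seqs, _lin, _tree = simdata.simulate_lineage_sequences(sim, rng=rng)
        aln = {k.rsplit("_", 1)[0]: v for k, v in seqs.items()}
        counts = dating.polarize_and_count_patterns(
            aln, ("SpB", "SpD", "SpC*", "SpC", "SpA")
        )
        est = dating.estimate_times_five_taxon(counts, strain="SpD")
        pd.DataFrame(
            [
                {
                    "region": "whole",
                    "strain": est.strain,
                    "n_sites": counts.n_sites,
                    "n_informative": counts.n_informative,
                    "T1": est.T1,
                    "T2": est.T2,
                }
            ]
        ).to_csv(out / "dating.tsv", sep="\t", index=False)
        row_counts["date"] = 1

    if "rearrange" in config.stages:
        labels = ["SpA", "SpB", "SpC", "SpC*", "SpD1", "SpD2"]
        topos = rearrange.enumerate_rooted_topologies(labels[: p["n_topology_leaves"]])
        true_topo = ((("SpB", ("SpD1", "SpD2")), ("SpC*", "SpC")), "SpA")
        events = simdata.random_rearrangement_events(
            true_topo, 5, (10, 10, 10), rng, reference="SpA"
        )
        perms, _truth = simdata.simulate_block_permutations(true_topo, events)
        (out / "permutations.grimm").write_text(write_grimm(perms))
        matrix = rearrange.permutations_to_characters(perms, reference="SpA")
        scores = rearrange.rank_topologies(topos, matrix)
        pd.DataFrame(
            [
                {
                    "rank": s.rank,
                    "topology": s.topology,
                    "total_changes": s.total_changes,
                    "n_conflicting": len(s.conflicting),
                }
                for s in scores[:20]
            ]
        ).to_csv(out / "topology_ranking.tsv", sep="\t", index=False)
        row_counts["rearrange"] = len(scores)

    if "f4" in config.stages:
        graph = models.m01_graph()
        freqs, _truth = simdata.simulate_graph_frequencies(graph, p["n_snps"], rng)
        observed = [
            popgen.compute_f4(freqs, q)
            for q in popgen.all_quadruples(models.POPULATIONS)
        ]
        fits = popgen.rank_models(models.candidate_models(), observed, n_restarts=3, rng=rng)
        pd.DataFrame(
            [
                {
                    "rank": f.rank,
                    "model": f.model_id,
                    "cost": f.cost,
                    "fit_fraction": f.fit_fraction,
                }
                for f in fits
            ]
        ).to_csv(out / "model_ranking.tsv", sep="\t", index=False)
        row_counts["f4"] = len(fits)

    if "growth" in config.stages:
        effects = {
            ("SpB", "glucose"): (4.0, 0.15, 30.0),
            ("SpC*", "glucose"): (6.0, 0.15, 30.0),
            ("SpD", "glucose"): (5.0, 0.15, 30.0),
        }
        gsim = simdata.SimConfig(seed=config.seed, n_strains_per_lineage=4)
        raw, _truth = simdata.simulate_growth_dataset(gsim, effects, rng=rng)
        rows = []
        for (strain, cond), sub in raw.groupby(["strain", "condition"]):
            curve = growth.build_growth_curve(sub, strain=strain, condition=cond)
            m = growth.compute_growth_metrics(
                curve,
                window=p["slope_window"],
                r_min=p["r_min"],
                slope_percentile=p["slope_percentile"],
            )
            lineage = sub["lineage"].iloc[0]
            rows.append(
                {
                    "strain": strain,
                    "lineage": lineage,
                    "condition": cond,
                    "AUC": m.AUC,
                    "MS": m.MS,
                    "ECS": m.ECS,
                }
            )
        metrics = pd.DataFrame(rows)
        d_rows = []
        for _i, r in metrics.iterrows():
            score = growth.midparent_d(
                r["AUC"],
                metrics.loc[metrics["lineage"] == "SpB", "AUC"],
                metrics.loc[metrics["lineage"] == "SpC*", "AUC"],
                strain=r["strain"],
                condition=r["condition"],
            )
            d_rows.append(
                {
                    "strain": r["strain"],
                    "lineage": r["lineage"],
                    "condition": r["condition"],
                    "d": score.d,
                }
            )
        d_table = pd.DataFrame(d_rows)
        tests, transgressive = growth.compare_hybrid_to_parents(
            d_table, "SpD", ("SpB", "SpC*")
        )
        metrics.to_csv(out / "growth_metrics.tsv", sep="\t", index=False)
        d_table.to_csv(out / "growth_d.tsv", sep="\t", index=False)
        tests.to_csv(out / "growth_tests.tsv", sep="\t", index=False)
        row_counts["growth"] = len(metrics)

    if "quantseq" in config.stages:
        n_genes = p["n_genes"]
        genes = [
            quantseq.GeneModel(f"g{i:03d}", "chrQ", 3000 * i + 500, 3000 * i + 1500, "+")
            for i in range(n_genes)
        ]
        counts = {g.gene_id: int(rng.integers(20, 500)) for g in genes}
        cov, truth = simdata.simulate_coverage_track(
            genes, counts, chrom_length=3000 * n_genes + 2000, rng=rng
        )
        track = quantseq.CoverageTrack("chrQ", cov)
        table = quantseq.count_genes(track, genes, footprint=50)
        table["true_count"] = [truth[g] for g in table["gene_id"]]
        table.to_csv(out / "quantseq_counts.tsv", sep="\t", index=False)
        row_counts["quantseq"] = len(table)

    checksums = {
        f.name: _checksum(f) for f in sorted(out.iterdir()) if f.is_file() and f.suffix != ".json"
    }
    manifest = RunManifest(
        seed=config.seed,
        config={"stages": list(config.stages), **config.effective},
        row_counts=row_counts,
        checksums=checksums,
        started=started,
        finished=time.time(),
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
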