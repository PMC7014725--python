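"""Orchestration: file-level runs of the TU and DE analyses.

Each run writes plain-text reports (TSV + JSON) into an output directory and
embeds a sha256 hash of the parameters so reports are traceable to their
configuration. The functions here are thin glue over the library modules;
:mod:`tucast.cli` exposes them as subcommands.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import annotation, boundaries as bnd, de, lmb, quant, simulate, tu
from .errors import InputError
from .models import DEConfig
from .trackio import (
    read_bedgraph_pair,
    read_boundaries_tsv,
    read_evidence_tsv,
    write_links_tsv,
)

log = logging.getLogger("tucast")


def config_hash(params: dict) -> str:
    return hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=str) + "\n")


def _tu_report(stages: dict[str, tu.Partition], genes, params: dict) -> dict:
    labeled = tu.label_units(stages["stage3"], genes)
    return {
        "config_sha256": config_hash(params),
        "n_genes": len(genes),
        "n_units": {k: len(v) for k, v in stages.items()},
        "stages": {k: [list(u) for u in v] for k, v in stages.items()},
        "transcription_units": [
            {
                "tu_id": u.tu_id,
                "genes": list(u.genes),
                "strand": u.strand,
                "cistron_class": u.cistron_class,
            }
            for u in labeled
        ],
    }


def run_tu(
    gff3: str,
    fasta: str,
    outdir: str,
    boundaries_tsv: str | None = None,
    bedgraph_plus: str | None = None,
    bedgraph_minus: str | None = None,
    fpkm_tsv: str | None = None,
    evidence_tsv: str | None = None,
    jump_factor: float = tu.DEFAULT_JUMP_FACTOR,
    similar_factor: float = tu.DEFAULT_SIMILAR_FACTOR,
) -> dict:
    """Three-stage TU inference from files.

    Boundaries come either from a TSV of calls or are detected from a pair
    of stranded bedGraph tracks; FPKM comes from a TSV or, failing that,
    from mean coverage. Stage-wise partitions are all serialized.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    params = dict(
        gff3=gff3, fasta=fasta, boundaries=boundaries_tsv,
        bedgraph=(bedgraph_plus, bedgraph_minus), fpkm=fpkm_tsv,
        evidence=evidence_tsv, jump_factor=jump_factor,
        similar_factor=similar_factor,
    )
    genes, genome = annotation.read_annotation(gff3, fasta)
    links = annotation.detect_overlap_links(genes, genome)
    write_links_tsv(links, out / "overlap_links.tsv")

    coverage = None
    if bedgraph_plus and bedgraph_minus:
        coverage = read_bedgraph_pair(
            bedgraph_plus, bedgraph_minus, {c: len(s) for c, s in genome.items()}
        )
    if boundaries_tsv:
        calls = read_boundaries_tsv(boundaries_tsv)
    elif coverage is not None:
        calls = bnd.detect_boundaries(coverage)
    else:
        raise InputError("need either a boundaries TSV or bedGraph coverage")

    if fpkm_tsv:
        fpkm = pd.read_csv(fpkm_tsv, sep="\t", index_col=0).iloc[:, 0].to_dict()
    elif coverage is not None:
        fpkm = quant.fpkm_from_coverage(coverage, genes)
    else:
        raise InputError("need either an FPKM TSV or bedGraph coverage")

    stage1 = tu.stage1_coupling_partition(genes, links)
    stage2 = tu.stage2_boundary_fpkm_merge(
        stage1, genes, calls, fpkm, jump_factor, similar_factor
    )
    evidence = read_evidence_tsv(evidence_tsv) if evidence_tsv else []
    stage3 = tu.stage3_junction_refine(stage2, genes, evidence)
    stages = {"stage1": stage1, "stage2": stage2, "stage3": stage3}
    report = _tu_report(stages, genes, params)
    _write_json(report, out / "tu_report.json")
    pd.DataFrame(report["transcription_units"]).assign(
        genes=lambda d: d["genes"].map(",".join)
    ).to_csv(out / "transcription_units.tsv", sep="\t", index=False)
    log.info(
        "TU inference: %d genes -> %d / %d / %d units",
        len(genes), len(stage1), len(stage2), len(stage3),
    )
    return report


def run_de(
    counts_tsv: str,
    outdir: str,
    totals: tuple[float, float] | None = None,
    cluster_genes: list[str] | None = None,
    categories_tsv: str | None = None,
    config: DEConfig | None = None,
) -> dict:
    """Two-library differential expression from a counts TSV."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or DEConfig()
    params = dict(
        counts=counts_tsv, totals=totals, categories=categories_tsv,
        lfc_threshold=config.lfc_threshold, p_threshold=config.p_threshold,
        method=config.method,
    )
    counts = pd.read_csv(counts_tsv, sep="\t")
    results = de.differential_expression(counts, totals=totals, config=config)
    results.to_csv(out / "de_results.tsv", sep="\t")
    de.volcano_table(results).to_csv(out / "volcano.tsv", sep="\t")
    categories = {}
    if categories_tsv:
        cat = pd.read_csv(categories_tsv, sep="\t", index_col=0)
        categories = cat.iloc[:, 0].to_dict()
    report = de.regulon_report(results, set(cluster_genes or []), categories)
    report["config_sha256"] = config_hash(params)
    report["thresholds"] = {
        "lfc": config.lfc_threshold, "p": config.p_threshold,
    }
    _write_json(report, out / "regulon_report.json")
    log.info(
        "DE: %d genes, %d down / %d up / %d excluded",
        len(results),
        int((results["status"] == "down").sum()),
        int((results["status"] == "up").sum()),
        int((results["status"] == "excluded").sum()),
    )
    return report


def run_demo(outdir: str, seed: int = 0) -> dict:
    """End-to-end demonstration on the encoded lmb cluster.

    Writes the fixture to standard formats, reruns the three TU stages from
    those files, then simulates a regulator-deletion transcriptome for a
    29-gene cluster and reports the differential calls. The TU stage counts
    trace the documented 29-gene -> 17 preliminary -> 15 final progression.
    """
    out = Path(outdir)
    fixture_dir = out / "lmb_fixture"
    paths = simulate.write_fixture_files(lmb.lmb_dataset(), fixture_dir)
    tu_report = run_tu(
        gff3=paths["gff3"],
        fasta=paths["fasta"],
        boundaries_tsv=paths["boundaries"],
        fpkm_tsv=paths["fpkm"],
        evidence_tsv=paths["evidence"],
        outdir=str(out / "tu"),
    )

    config = simulate.SimulationConfig(seed=seed)
    dataset = simulate.simulate_dataset(config)
    sim_dir = out / "synthetic"
    simulate.write_fixture_files(dataset, sim_dir)
    de_report = run_de(
        counts_tsv=str(sim_dir / "counts.tsv"),
        outdir=str(out / "de"),
        totals=(config.library_size, config.library_size),
        cluster_genes=dataset.truth.cluster_genes,
    )
    summary = {
        "config_sha256": config_hash({"seed": seed}),
        "tu_progression": tu_report["n_units"],
        "tu_composition": _composition(tu_report),
        "de_counts": de_report["counts"],
        "deleted_gene": dataset.truth.deleted_gene,
    }
    _write_json(summary, out / "demo_summary.json")
    return summary


def _composition(tu_report: dict) -> dict[str, int]:
    comp: dict[str, int] = {}
    for unit in tu_report["transcription_units"]:
        comp[unit["cistron_class"]] = comp.get(unit["cistron_class"], 0) + 1
    return comp
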