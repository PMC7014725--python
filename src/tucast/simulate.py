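"""Synthetic annotated genomes, stranded coverage and two-condition counts.

The generator emulates the data situation of a regulator-deletion study of a
highly expressed biosynthetic gene cluster: a compact cluster of genes
organized into known transcription units (some junctions translationally
coupled via stop-start overlaps), strand-specific per-base coverage with
step edges at unit boundaries and degressive expression along each unit,
and a pair of count libraries (original vs deletion strain) in which the
cluster genes collapse by a configured knockdown range, the deleted gene
itself drops to zero reads, and a handful of planted non-cluster genes move
up or down. Everything is driven by a single integer seed; identical
seed+config produce byte-identical outputs.

Counts are negative binomial (variance mu + dispersion*mu^2); coverage noise
is optionally Poisson. What the generator does *not* emulate: read-level
artifacts (mapping bias, rRNA carryover), operon-internal promoters firing
condition-dependently, and biological replicate variance.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .models import BoundaryCall, GeneModel, SyntheticTruth
from .trackio import (
    StrandedCoverage,
    revcomp,
    write_bedgraph,
    write_boundaries_tsv,
    write_evidence_tsv,
    write_fasta,
    write_gff3,
)

_BASES = np.array(list("ACGT"))

#: default cluster layout: 15 units / 29 genes mirroring a typical
#: antibiotic-biosynthesis cluster (mono/bi/tri/penta mix on both strands)
DEFAULT_TU_PLAN: tuple[tuple[str, int], ...] = (
    ("-", 1),
    ("+", 1),
    ("+", 2),
    ("-", 1),
    ("+", 1),
    ("-", 3),
    ("-", 2),
    ("+", 1),
    ("-", 3),
    ("-", 5),
    ("-", 3),
    ("+", 1),
    ("+", 3),
    ("-", 1),
    ("+", 1),
)


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions.

    ``base_expression`` is the FPKM-scale level of the first gene of each
    cluster unit (cluster genes dominate the transcriptome under production
    conditions -- quantifying a 99.98% decline requires original counts on
    the 1e4 scale); ``degression_factor`` multiplies it per step along a
    unit. ``knockdown_range`` is the percent decline applied to cluster
    genes in the deletion condition.
    """

    n_genes: int = 329  # cluster genes + non-cluster background genes
    tu_plan: tuple[tuple[str, int], ...] = DEFAULT_TU_PLAN
    intergenic_len_bp: tuple[int, int] = (150, 400)
    intra_tu_gap_bp: tuple[int, int] = (15, 80)
    coupled_overlap_bp: tuple[int, ...] = (4, 8)
    coupled_fraction: float = 0.6  # probability an intra-unit junction overlaps
    gene_len_bp: tuple[int, int] = (300, 1500)
    base_expression: float = 2e4
    expression_sigma: float = 0.5  # lognormal spread of per-unit base levels
    degression_factor: float = 0.85
    dispersion: float = 0.1  # NB: var = mu + dispersion * mu^2
    library_size: float = 1e6
    knockdown_range: tuple[float, float] = (93.71, 99.98)
    n_up_noncluster: int = 1
    n_down_noncluster: int = 19
    up_log2fc: float = 5.8
    down_log2fc_range: tuple[float, float] = (2.5, 5.4)
    background_expression: float = 50.0
    noise: bool = True  # False: counts are their rounded means
    coverage_noise: bool = False  # True: Poisson per-base depth
    deleted_gene: str | None = None  # default: first gene of the 13th unit
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.knockdown_range
        if not (0 < lo <= hi < 100):
            raise ConfigError("knockdown_range must lie inside (0, 100)")
        if not (0 < self.degression_factor <= 1):
            raise ConfigError("degression_factor must be in (0, 1]")
        if self.library_size <= 0:
            raise ConfigError("library_size must be positive")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if any(k not in (4, 8) for k in self.coupled_overlap_bp):
            raise ConfigError("coupled overlaps must be 4 or 8 bp")
        if min(self.gene_len_bp) <= max(self.coupled_overlap_bp):
            raise ConfigError("overlap longer than a CDS: infeasible layout")
        if self.n_cluster_genes > self.n_genes:
            raise ConfigError("n_genes smaller than the tu_plan gene count")
        if self.n_up_noncluster + self.n_down_noncluster > self.n_background:
            raise ConfigError("more planted non-cluster genes than background genes")

    @property
    def n_cluster_genes(self) -> int:
        return sum(k for _, k in self.tu_plan)

    @property
    def n_background(self) -> int:
        return self.n_genes - self.n_cluster_genes


# ---------------------------------------------------------------------------
# genome assembly


@dataclass(frozen=True)
class GeneSpec:
    """One gene in a left-to-right layout.

    ``overlap`` > 0 places the gene's first ``overlap`` bases on top of the
    previous gene's last bases and requires ``motif`` of exactly that length
    (sense orientation; e.g. ATGA/GTGA for 4 bp) to be stamped over the
    junction so that the stop and start codons are real.
    """

    gene_id: str
    strand: str
    length: int
    gap_before: int = 0
    overlap: int = 0
    motif: str | None = None


def assemble_genome(
    specs: list[GeneSpec],
    contig: str,
    rng: np.random.Generator,
    lead: int = 500,
    tail: int = 500,
) -> tuple[str, list[GeneModel]]:
    """Lay genes left-to-right and build the corresponding sequence.

    Gene bodies start with ATG and end with TGA (sense strand); coupled
    junction motifs are stamped last so both codons of a stop-start overlap
    are intact. Raises :class:`ConfigError` for infeasible layouts.
    """
    genes: list[GeneModel] = []
    prev_end = lead
    for spec in specs:
        if spec.length % 3:
            raise ConfigError(f"{spec.gene_id}: CDS length must be a multiple of 3")
        if spec.overlap:
            if not genes:
                raise ConfigError(f"{spec.gene_id}: first gene cannot overlap")
            prev = genes[-1]
            if prev.strand != spec.strand:
                raise ConfigError(f"{spec.gene_id}: overlap across strands")
            if spec.overlap >= min(prev.length, spec.length):
                raise ConfigError(f"{spec.gene_id}: overlap longer than a CDS")
            if spec.motif is None or len(spec.motif) != spec.overlap:
                raise ConfigError(f"{spec.gene_id}: motif must match overlap length")
            start = prev_end - spec.overlap + 1
        else:
            start = prev_end + spec.gap_before + 1
        end = start + spec.length - 1
        genes.append(GeneModel(spec.gene_id, contig, start, end, spec.strand))
        prev_end = end

    total = prev_end + tail
    seq = rng.choice(_BASES, size=total)
    for spec, gene in zip(specs, genes):
        body = "ATG" + "".join(rng.choice(_BASES, size=gene.length - 6)) + "TGA"
        if gene.strand == "-":
            body = revcomp(body)
        seq[gene.start - 1 : gene.end] = list(body)
    for spec, gene in zip(specs, genes):  # junction motifs win over bodies
        if spec.overlap:
            motif = spec.motif if gene.strand == "+" else revcomp(spec.motif)
            lo = gene.start if gene.strand == "+" else gene.start
            seq[lo - 1 : lo - 1 + spec.overlap] = list(motif)
    return "".join(seq), genes


def _junction_motif(overlap: int, rng: np.random.Generator) -> str:
    if overlap == 4:
        return str(rng.choice(["ATGA", "GTGA"]))
    # 8 bp: start codon at positions 1-3, stop codon at 6-8
    return "ATG" + "".join(rng.choice(_BASES, size=2)) + "TGA"


# ---------------------------------------------------------------------------
# generator operations


def generate_annotation(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel], SyntheticTruth]:
    """Build the annotated genome and its ground truth.

    The cluster occupies contig ``cluster``; non-cluster background genes sit
    head-to-tail on contig ``background`` as monocistrons. Within a planned
    unit, each junction is translationally coupled (stop-start overlap of a
    configured length) with probability ``coupled_fraction``, otherwise it is
    a short co-transcribed gap.
    """
    rng = np.random.default_rng([config.seed, 1])
    width = len(str(config.n_cluster_genes))
    specs: list[GeneSpec] = []
    tus_genomic: list[list[str]] = []
    idx = 0
    for strand, k in config.tu_plan:
        unit: list[str] = []
        for j in range(k):
            idx += 1
            gid = f"g{idx:0{width}d}"
            unit.append(gid)
            length = 3 * int(rng.integers(
                config.gene_len_bp[0] // 3, config.gene_len_bp[1] // 3 + 1
            ))
            if j == 0:
                specs.append(
                    GeneSpec(
                        gid,
                        strand,
                        length,
                        gap_before=int(rng.integers(*config.intergenic_len_bp)),
                    )
                )
            elif rng.random() < config.coupled_fraction:
                ov = int(rng.choice(config.coupled_overlap_bp))
                specs.append(
                    GeneSpec(gid, strand, length, overlap=ov,
                             motif=_junction_motif(ov, rng))
                )
            else:
                specs.append(
                    GeneSpec(
                        gid,
                        strand,
                        length,
                        gap_before=int(rng.integers(*config.intra_tu_gap_bp)),
                    )
                )
        tus_genomic.append(unit)
    cluster_seq, cluster_genes = assemble_genome(specs, "cluster", rng)

    bg_specs = [
        GeneSpec(
            f"bg{i + 1:03d}",
            "+" if i % 2 == 0 else "-",
            3 * int(rng.integers(
                config.gene_len_bp[0] // 3, config.gene_len_bp[1] // 3 + 1
            )),
            gap_before=int(rng.integers(*config.intergenic_len_bp)),
        )
        for i in range(config.n_background)
    ]
    bg_seq, bg_genes = assemble_genome(bg_specs, "background", rng)

    genes = cluster_genes + bg_genes
    by_id = {g.gene_id: g for g in genes}

    # transcription-ordered units + boundaries
    true_tus: list[list[str]] = []
    boundaries: list[BoundaryCall] = []
    for unit in tus_genomic:
        strand = by_id[unit[0]].strand
        tx = unit if strand == "+" else unit[::-1]
        true_tus.append(tx)
        first, last = by_id[tx[0]], by_id[tx[-1]]
        boundaries.append(BoundaryCall(first.tx_start, strand, "TSS"))
        boundaries.append(BoundaryCall(last.tx_end, strand, "TTS"))
    true_tus += [[g.gene_id] for g in bg_genes]

    # expression truth
    fpkm: dict[str, float] = {}
    for unit in true_tus[: len(config.tu_plan)]:
        base = config.base_expression * rng.lognormal(0.0, config.expression_sigma)
        for i, gid in enumerate(unit):
            fpkm[gid] = base * config.degression_factor**i
    for g in bg_genes:
        fpkm[g.gene_id] = config.background_expression * rng.lognormal(
            0.0, config.expression_sigma
        )

    cluster_ids = [g.gene_id for g in cluster_genes]
    deleted = config.deleted_gene
    if deleted is None and config.tu_plan:
        # default: first gene of the regulator-carrying unit (13th when the
        # plan is long enough, mirroring a mid/late-cluster regulator gene)
        unit13 = true_tus[min(12, len(config.tu_plan) - 1)]
        deleted = unit13[0]
    if deleted is not None and deleted not in by_id:
        raise ConfigError(f"deleted_gene {deleted!r} is not a generated gene")

    status = {g.gene_id: "unchanged" for g in genes}
    for gid in cluster_ids:
        status[gid] = "down"
    n_planted = config.n_up_noncluster + config.n_down_noncluster
    if n_planted:
        planted = rng.choice(
            [g.gene_id for g in bg_genes], size=n_planted, replace=False
        )
        for gid in planted[: config.n_up_noncluster]:
            status[gid] = "up"
        for gid in planted[config.n_up_noncluster :]:
            status[gid] = "down"

    truth = SyntheticTruth(
        true_tus=true_tus,
        true_status=status,
        true_boundaries=boundaries,
        genes=genes,
        true_fpkm=fpkm,
        deleted_gene=deleted,
        cluster_genes=cluster_ids,
    )
    genome = {"cluster": cluster_seq, "background": bg_seq}
    return genome, genes, truth


def generate_coverage(
    truth: SyntheticTruth, config: SimulationConfig
) -> StrandedCoverage:
    """Stranded per-base depth: plateaus at each gene's FPKM-scale level,
    read-through filling intra-unit gaps, near-zero elsewhere."""
    by_id = {g.gene_id: g for g in truth.genes}
    lengths: dict[str, int] = {}
    for g in truth.genes:
        lengths[g.contig] = max(lengths.get(g.contig, 0), g.end + 500)
    cov = StrandedCoverage.zeros(lengths)
    for unit in truth.true_tus:
        strand = by_id[unit[0]].strand
        track = cov.get(by_id[unit[0]].contig, strand)
        prev: GeneModel | None = None
        for gid in unit:  # transcription order
            g = by_id[gid]
            level = truth.true_fpkm[gid]
            seg = track[g.start - 1 : g.end]
            np.maximum(seg, level, out=seg)
            if prev is not None:  # fill the intra-unit gap with read-through
                lo = min(prev.end, g.end)
                hi = max(prev.start, g.start)
                if hi - lo > 1:
                    gap = track[lo : hi - 1]
                    np.maximum(gap, truth.true_fpkm[prev.gene_id], out=gap)
            prev = g
    if config.coverage_noise:
        rng = np.random.default_rng([config.seed, 2])
        for contig in cov.contigs():
            for strand in ("+", "-"):
                arr = cov.get(contig, strand)
                arr[:] = rng.poisson(arr)
    return cov


def _expected_means(
    truth: SyntheticTruth, config: SimulationConfig, condition: str
) -> pd.Series:
    by_id = {g.gene_id: g for g in truth.genes}
    mu = pd.Series(
        {
            gid: truth.true_fpkm[gid] * by_id[gid].length * config.library_size / 1e9
            for gid in (g.gene_id for g in truth.genes)
        }
    )
    if condition == "original":
        return mu
    kd_rng = np.random.default_rng([config.seed, 3])
    lo, hi = config.knockdown_range
    for gid in truth.cluster_genes:
        mu[gid] *= 1 - kd_rng.uniform(lo, hi) / 100
    if truth.deleted_gene is not None:
        mu[truth.deleted_gene] = 0.0
    fc_rng = np.random.default_rng([config.seed, 4])
    for gid, st in truth.true_status.items():
        if gid in set(truth.cluster_genes):
            continue
        if st == "up":
            mu[gid] *= 2**config.up_log2fc
        elif st == "down":
            mu[gid] *= 2 ** -fc_rng.uniform(*config.down_log2fc_range)
    return mu


def generate_counts(
    truth: SyntheticTruth, config: SimulationConfig, condition: str
) -> pd.Series:
    """Readcounts for one condition (``original`` or ``deletion``).

    Means are FPKM * length_bp * library_size / 1e9; the deletion condition
    applies per-gene knockdowns drawn once per config from
    ``knockdown_range``, zeroes the deleted gene, and scales planted
    non-cluster genes by their fold changes. Counts are negative binomial
    (Poisson when dispersion is 0); with ``noise=False`` they equal their
    rounded means.
    """
    if condition not in ("original", "deletion"):
        raise InputError(f"unknown condition {condition!r}")
    mu = _expected_means(truth, config, condition)
    if not config.noise:
        return mu.round()
    rng = np.random.default_rng([config.seed, 5 if condition == "original" else 6])
    vals = mu.to_numpy()
    out = np.zeros_like(vals)
    pos = vals > 0
    if config.dispersion == 0:
        out[pos] = rng.poisson(vals[pos])
    else:
        n = 1.0 / config.dispersion
        p = n / (n + vals[pos])
        out[pos] = rng.negative_binomial(n, p)
    return pd.Series(out, index=mu.index)


# ---------------------------------------------------------------------------
# bundling and file output


@dataclass
class Dataset:
    """Everything one run of the generator (or the cluster fixture) knows."""

    genome: dict[str, str]
    genes: list[GeneModel]
    truth: SyntheticTruth | None = None
    coverage: StrandedCoverage | None = None
    counts: pd.DataFrame | None = None  # columns count_orig / count_mut
    boundaries: list[BoundaryCall] = field(default_factory=list)
    evidence: list = field(default_factory=list)
    fpkm: dict[str, float] = field(default_factory=dict)


def simulate_dataset(config: SimulationConfig) -> Dataset:
    """Run the full generator: annotation, coverage and both count libraries."""
    genome, genes, truth = generate_annotation(config)
    coverage = generate_coverage(truth, config)
    counts = pd.DataFrame(
        {
            "count_orig": generate_counts(truth, config, "original"),
            "count_mut": generate_counts(truth, config, "deletion"),
        }
    )
    counts.index.name = "gene_id"
    return Dataset(
        genome=genome,
        genes=genes,
        truth=truth,
        coverage=coverage,
        counts=counts,
        boundaries=list(truth.true_boundaries),
        fpkm=dict(truth.true_fpkm),
    )


def write_fixture_files(dataset: Dataset, directory: str | os.PathLike) -> dict:
    """Serialize a dataset to standard text formats.

    GFF3 + FASTA for the annotation, one bedGraph per strand for coverage,
    TSV for counts / boundaries / evidence / FPKM / truth. Returns a mapping
    of logical name to written path.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        probe = directory / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise InputError(f"cannot write to {directory}: {exc}") from exc

    paths: dict[str, Path] = {}

    def _path(name: str, fname: str) -> Path:
        paths[name] = directory / fname
        return paths[name]

    write_fasta(dataset.genome, _path("fasta", "genome.fasta"))
    write_gff3(dataset.genes, _path("gff3", "annotation.gff3"))
    if dataset.coverage is not None:
        write_bedgraph(dataset.coverage, "+", _path("bedgraph_plus", "coverage_plus.bedgraph"))
        write_bedgraph(dataset.coverage, "-", _path("bedgraph_minus", "coverage_minus.bedgraph"))
    if dataset.counts is not None:
        dataset.counts.to_csv(_path("counts", "counts.tsv"), sep="\t")
    if dataset.boundaries:
        write_boundaries_tsv(dataset.boundaries, _path("boundaries", "boundaries.tsv"))
    if dataset.evidence:
        write_evidence_tsv(dataset.evidence, _path("evidence", "evidence.tsv"))
    if dataset.fpkm:
        pd.Series(dataset.fpkm, name="fpkm").rename_axis("gene_id").to_csv(
            _path("fpkm", "fpkm.tsv"), sep="\t"
        )
    if dataset.truth is not None:
        rows = [
            {"tu_index": i + 1, "genes": ",".join(unit)}
            for i, unit in enumerate(dataset.truth.true_tus)
        ]
        pd.DataFrame(rows).to_csv(_path("true_tus", "true_tus.tsv"), sep="\t", index=False)
        pd.Series(dataset.truth.true_status, name="status").rename_axis(
            "gene_id"
        ).to_csv(_path("true_status", "true_status.tsv"), sep="\t")
    return {k: str(v) for k, v in paths.items()}


def config_as_dict(config: SimulationConfig) -> dict:
    return dataclasses.asdict(config)
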