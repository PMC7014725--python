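"""Synthetic encoding of the lincomycin biosynthetic (*lmb*) gene cluster.

*Streptomyces lincolnensis* carries a 29-ORF cluster (three resistance genes
lmrA/lmrB/lmrC plus 26 biosynthetic/regulatory lmb genes) whose transcription
units were characterized by strand-specific RNA-seq and RT-PCR. This module
hard-codes that evidence so the inference pipeline can be exercised and
tested end-to-end without sequencing data:

* gene order and stop-start overlap structure: lmbB1-B2 (4 bp), lmbF-G
  (4 bp), lmbIH-J (8 bp), the lmbL-M-N-Z-P-O chain (4 bp each), lmbS-R
  (4 bp), lmbQ-T-V (4 bp each) and lmbY-X (4 bp, AUGA);
* start-type boundary predictions upstream of lmbA, lmbB1, lmbE, the lmbG
  and lmbJ groups, lmbO, lmbU and lmbY (reported upstream "TTS" bent arrows
  are recorded as start-type calls, which is what their placement implies);
* an FPKM table and RT-PCR junction-evidence rows.

Coordinates, strand assignments of the standalone genes and FPKM magnitudes
are SYNTHETIC stand-ins: only the gene order, the overlap lengths, the
boundary placements, the junction evidence and the qualitative expression
relations (lmbB1 >> lmbA; lmbE ~ lmbG; degressive series V->T->Q, R->Z,
N->M->L, U->Y->X; lmbN/M/L >> lmbR..Z) are treated as contractual.
"Much larger" is encoded as >= 4-fold and "not significantly different" as
within 2-fold, matching the inference defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import detect_overlap_links
from .models import BoundaryCall, GeneModel, JunctionEvidence, OverlapLink
from .simulate import Dataset, GeneSpec, assemble_genome

CONTIG = "lmb"

#: 29 cluster ORFs in genomic order
LMB_GENE_ORDER = (
    "lmrA", "lmbA", "lmbB1", "lmbB2", "lmbC", "lmbD", "lmbE", "lmbF", "lmbG",
    "lmbIH", "lmbJ", "lmbK", "lmbL", "lmbM", "lmbN", "lmbZ", "lmbP", "lmbO",
    "lmbS", "lmbR", "lmbQ", "lmbT", "lmbV", "lmbW", "lmbU", "lmbY", "lmbX",
    "lmrB", "lmrC",
)

# (gene, strand, CDS length, gap before gene, overlap with previous, motif)
# The lmbU-lmbY gap is the documented 145 bp; other gaps are synthetic.
_LAYOUT: tuple[tuple[str, str, int, int, int, str | None], ...] = (
    ("lmrA", "-", 1446, 0, 0, None),
    ("lmbA", "+", 933, 200, 0, None),
    ("lmbB1", "+", 513, 100, 0, None),
    ("lmbB2", "+", 852, 0, 4, "ATGA"),
    ("lmbC", "-", 1482, 250, 0, None),
    ("lmbD", "+", 906, 250, 0, None),
    ("lmbE", "-", 852, 250, 0, None),
    ("lmbF", "-", 1239, 80, 0, None),
    ("lmbG", "-", 753, 0, 4, "GTGA"),
    ("lmbIH", "-", 1848, 80, 0, None),
    ("lmbJ", "-", 672, 0, 8, "ATGCGTGA"),
    ("lmbK", "+", 528, 300, 0, None),
    ("lmbL", "-", 1050, 300, 0, None),
    ("lmbM", "-", 1404, 0, 4, "ATGA"),
    ("lmbN", "-", 1740, 0, 4, "GTGA"),
    ("lmbZ", "-", 972, 0, 4, "ATGA"),
    ("lmbP", "-", 1044, 0, 4, "ATGA"),
    ("lmbO", "-", 729, 0, 4, "GTGA"),
    ("lmbS", "-", 1224, 50, 0, None),
    ("lmbR", "-", 687, 0, 4, "ATGA"),
    ("lmbQ", "-", 714, 50, 0, None),
    ("lmbT", "-", 1104, 0, 4, "ATGA"),
    ("lmbV", "-", 729, 0, 4, "GTGA"),
    ("lmbW", "+", 726, 300, 0, None),
    ("lmbU", "+", 657, 300, 0, None),
    ("lmbY", "+", 750, 145, 0, None),
    ("lmbX", "+", 801, 0, 4, "ATGA"),
    ("lmrB", "-", 1476, 250, 0, None),
    ("lmrC", "+", 1551, 250, 0, None),
)

#: synthetic FPKM magnitudes satisfying the documented qualitative relations
LMB_FPKM: dict[str, float] = {
    "lmrA": 60, "lmbA": 50, "lmbB1": 2000, "lmbB2": 1700, "lmbC": 300,
    "lmbD": 250, "lmbE": 100, "lmbF": 110, "lmbG": 120, "lmbIH": 400,
    "lmbJ": 500, "lmbK": 80, "lmbL": 4000, "lmbM": 5000, "lmbN": 6000,
    "lmbZ": 250, "lmbP": 350, "lmbO": 500, "lmbS": 700, "lmbR": 900,
    "lmbQ": 200, "lmbT": 300, "lmbV": 400, "lmbW": 150, "lmbU": 800,
    "lmbY": 600, "lmbX": 450, "lmrB": 70, "lmrC": 90,
}

#: RT-PCR junction evidence (upstream gene, downstream gene in transcription
#: order, detected). Detection of lmbF/lmbG from lmbE-primed cDNA, of lmbJ
#: from lmbIH, of lmbN from lmbL, of lmbR/lmbO from lmbZ, and of lmbU from
#: lmbX-primed cDNA; lmbIH undetected from lmbE and lmbZ undetected from
#: lmbL confirm the corresponding splits.
LMB_EVIDENCE: tuple[tuple[str, str, bool], ...] = (
    ("lmbF", "lmbE", True),
    ("lmbG", "lmbF", True),
    ("lmbIH", "lmbG", False),
    ("lmbJ", "lmbIH", True),
    ("lmbN", "lmbM", True),
    ("lmbZ", "lmbN", False),
    ("lmbS", "lmbO", True),
    ("lmbR", "lmbS", True),
    ("lmbU", "lmbY", True),
)

#: the 15 characterized transcription units, transcription order per unit
LMB_FINAL_TUS: tuple[tuple[str, ...], ...] = (
    ("lmrA",), ("lmbA",), ("lmbB1", "lmbB2"), ("lmbC",), ("lmbD",),
    ("lmbG", "lmbF", "lmbE"), ("lmbJ", "lmbIH"), ("lmbK",),
    ("lmbN", "lmbM", "lmbL"), ("lmbR", "lmbS", "lmbO", "lmbP", "lmbZ"),
    ("lmbV", "lmbT", "lmbQ"), ("lmbW",), ("lmbU", "lmbY", "lmbX"),
    ("lmrB",), ("lmrC",),
)


@dataclass
class LmbFixture:
    genome: dict[str, str]
    genes: list[GeneModel]
    links: list[OverlapLink]
    boundaries: list[BoundaryCall] = field(default_factory=list)
    fpkm: dict[str, float] = field(default_factory=dict)
    evidence: list[JunctionEvidence] = field(default_factory=list)


def lmb_fixture() -> LmbFixture:
    """Build the cluster fixture (deterministic; no configuration).

    Returns gene models in genomic order, overlap links derived from the
    assembled sequence, the stated boundary calls, the FPKM table and the
    RT-PCR junction evidence.
    """
    rng = np.random.default_rng(29)
    specs = [
        GeneSpec(gid, strand, length, gap_before=gap, overlap=ov, motif=motif)
        for gid, strand, length, gap, ov, motif in _LAYOUT
    ]
    seq, genes = assemble_genome(specs, CONTIG, rng)
    genome = {CONTIG: seq}
    links = detect_overlap_links(genes, genome)
    by_id = {g.gene_id: g for g in genes}

    def tss_plus(gene: str) -> BoundaryCall:
        return BoundaryCall(by_id[gene].start - 30, "+", "TSS", 10.0)

    def tss_minus(gene: str) -> BoundaryCall:
        return BoundaryCall(by_id[gene].end + 30, "-", "TSS", 10.0)

    def tts(gene: str) -> BoundaryCall:
        g = by_id[gene]
        pos = g.end + 30 if g.strand == "+" else g.start - 30
        return BoundaryCall(pos, g.strand, "TTS", 10.0)

    boundaries = sorted(
        [
            # start-type predictions at unit upstreams
            tss_plus("lmbA"), tss_plus("lmbB1"), tss_minus("lmbE"),
            tss_minus("lmbG"), tss_minus("lmbJ"), tss_minus("lmbO"),
            tss_plus("lmbU"), tss_plus("lmbY"),
            # step-down calls at unit downstream ends (inert for merging)
            tts("lmrA"), tts("lmbA"), tts("lmbB2"), tts("lmbC"), tts("lmbD"),
            tts("lmbE"), tts("lmbIH"), tts("lmbK"), tts("lmbL"), tts("lmbQ"),
            tts("lmbW"), tts("lmbX"), tts("lmrB"), tts("lmrC"),
        ],
        key=lambda b: b.position,
    )
    evidence = [JunctionEvidence(f, t, d) for f, t, d in LMB_EVIDENCE]
    return LmbFixture(
        genome=genome,
        genes=genes,
        links=links,
        boundaries=boundaries,
        fpkm=dict(LMB_FPKM),
        evidence=evidence,
    )


def lmb_dataset() -> Dataset:
    """The fixture as a :class:`~tucast.simulate.Dataset` for file output."""
    fx = lmb_fixture()
    return Dataset(
        genome=fx.genome,
        genes=fx.genes,
        boundaries=fx.boundaries,
        evidence=fx.evidence,
        fpkm=fx.fpkm,
    )
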