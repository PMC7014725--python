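"""Annotation input and translational-coupling detection.

In compact bacterial gene clusters, consecutive genes frequently overlap by a
few base pairs so that the stop codon of the upstream cistron and the start
codon of the downstream cistron interleave (canonically the ATGA or GTGA
tetranucleotide for a 4-bp overlap). Such stop-start overlaps couple
translation of the two cistrons and imply that they are transcribed together;
they are the strongest purely sequence-derived evidence used by the
transcription-unit inference in :mod:`tucast.tu`.
"""

from __future__ import annotations

import os
from collections.abc import Mapping, Sequence

import gffutils

from .errors import InputError
from .models import GeneModel, OverlapLink
from .trackio import read_fasta, revcomp

#: overlaps longer than this are reported but not treated as coupling
#: (very long overlaps are usually annotation artifacts)
MAX_COUPLED_OVERLAP = 12


def read_annotation(
    gff3_path: str | os.PathLike, fasta_path: str | os.PathLike
) -> tuple[list[GeneModel], dict[str, str]]:
    """Read CDS features and genome sequence.

    Returns genes sorted by (contig, start) and the contig sequences.
    Raises :class:`InputError` for malformed files or CDS outside sequence
    bounds.
    """
    genome = read_fasta(fasta_path)
    with open(gff3_path) as fh:
        has_features = any(
            line.strip() and not line.startswith("#") for line in fh
        )
    if not has_features:
        return [], genome
    try:
        db = gffutils.create_db(
            str(gff3_path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise InputError(f"cannot parse GFF3 {gff3_path}: {exc}") from exc

    genes: list[GeneModel] = []
    for feat in db.features_of_type("CDS"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        if feat.seqid not in genome:
            raise InputError(f"gene {gene_id}: contig {feat.seqid!r} not in FASTA")
        if feat.end > len(genome[feat.seqid]) or feat.start < 1:
            raise InputError(
                f"gene {gene_id}: [{feat.start}, {feat.end}] outside contig "
                f"{feat.seqid!r} of length {len(genome[feat.seqid])}"
            )
        genes.append(
            GeneModel(
                gene_id=gene_id,
                contig=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
            )
        )
    genes.sort(key=lambda g: (g.contig, g.start, g.end))
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise InputError(f"duplicate gene id {g.gene_id!r}")
        seen.add(g.gene_id)
    return genes, genome


def _junction(up_stop: tuple[int, int], down_start: tuple[int, int]) -> tuple[int, int]:
    """Union span (1-based inclusive) of the stop and start codon intervals."""
    return min(up_stop[0], down_start[0]), max(up_stop[1], down_start[1])


def _shared_nt(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def detect_overlap_links(
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
    max_coupled_overlap: int = MAX_COUPLED_OVERLAP,
) -> list[OverlapLink]:
    """Find stop-start overlaps between adjacent same-strand genes.

    One candidate link is produced per adjacent same-strand pair whose
    coordinates overlap by >= 1 bp. The pair is ``coupled`` when the overlap
    is short (<= ``max_coupled_overlap`` bp); the junction sequence (sense
    strand, spanning both codons) and the number of nucleotides the stop and
    start codons share are reported alongside. Detection is purely local to
    the junction: sequence outside it never changes the link.
    """
    links: list[OverlapLink] = []
    ordered = sorted(genes, key=lambda g: (g.contig, g.start, g.end))
    for left, right in zip(ordered, ordered[1:]):
        if left.contig != right.contig or left.strand != right.strand:
            continue
        overlap = left.end - right.start + 1
        if overlap < 1:
            continue
        seq = genome[left.contig]
        if left.strand == "+":
            up, down = left, right
            stop = (up.end - 2, up.end)
            start = (down.start, down.start + 2)
            lo, hi = _junction(stop, start)
            junction = seq[lo - 1 : hi]
        else:
            up, down = right, left
            stop = (up.start, up.start + 2)  # genomic; 3' end of the minus CDS
            start = (down.end - 2, down.end)
            lo, hi = _junction(stop, start)
            junction = revcomp(seq[lo - 1 : hi])
        links.append(
            OverlapLink(
                upstream_gene=up.gene_id,
                downstream_gene=down.gene_id,
                overlap_bp=overlap,
                junction_seq=junction,
                coupled=overlap <= max_coupled_overlap,
                codon_shared_nt=_shared_nt(stop, start),
            )
        )
    return links
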