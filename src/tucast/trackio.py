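"""File formats and coordinate conversions.

All gene coordinates in this package are GFF3-style (1-based, inclusive);
per-base tracks are numpy arrays indexed 0-based; bedGraph intervals are
0-based half-open. The two helpers :func:`to0` and :func:`to1` are the only
place the conversion happens.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError
from .models import BoundaryCall, GeneModel, JunctionEvidence, OverlapLink

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def to0(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start1 - 1, end1


def to1(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start0 + 1, end0


class StrandedCoverage:
    """Per-base read depth, one float array per contig and strand."""

    def __init__(self, tracks: dict[str, dict[str, np.ndarray]]):
        self.tracks = tracks

    @classmethod
    def zeros(cls, contig_lengths: Mapping[str, int]) -> "StrandedCoverage":
        return cls(
            {
                c: {"+": np.zeros(n, float), "-": np.zeros(n, float)}
                for c, n in contig_lengths.items()
            }
        )

    def contigs(self) -> list[str]:
        return sorted(self.tracks)

    def length(self, contig: str) -> int:
        return len(self.tracks[contig]["+"])

    def get(self, contig: str, strand: str) -> np.ndarray:
        try:
            return self.tracks[contig][strand]
        except KeyError as exc:
            raise InputError(f"no track for {contig!r} strand {strand!r}") from exc


# ---------------------------------------------------------------------------
# FASTA / GFF3


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=contig, description="")
        for contig, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_gff3(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig}\ttucast\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t"
                f"ID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph (run-length text; one file per strand)


def write_bedgraph(
    coverage: StrandedCoverage, strand: str, path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for contig in coverage.contigs():
            arr = coverage.get(contig, strand)
            if arr.size == 0:
                continue
            # run-length encode
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{contig}\t{s}\t{e}\t{v:.10g}\n")


def read_bedgraph_pair(
    plus_path: str | os.PathLike,
    minus_path: str | os.PathLike,
    contig_lengths: Mapping[str, int],
) -> StrandedCoverage:
    cov = StrandedCoverage.zeros(contig_lengths)
    for strand, path in (("+", plus_path), ("-", minus_path)):
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("track", "#")):
                    continue
                try:
                    contig, s, e, v = line.split("\t")
                    s, e, v = int(s), int(e), float(v)
                except ValueError as exc:
                    raise InputError(f"{path}:{lineno}: bad bedGraph line") from exc
                if contig not in cov.tracks or e > cov.length(contig):
                    raise InputError(
                        f"{path}:{lineno}: interval outside contig {contig!r}"
                    )
                cov.get(contig, strand)[s:e] = v
    return cov


# ---------------------------------------------------------------------------
# TSV tables


def write_links_tsv(links: Iterable[OverlapLink], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("upstream\tdownstream\toverlap_bp\tjunction_seq\tcoupled\n")
        for ln in links:
            fh.write(
                f"{ln.upstream_gene}\t{ln.downstream_gene}\t{ln.overlap_bp}\t"
                f"{ln.junction_seq}\t{ln.coupled}\n"
            )


def write_boundaries_tsv(
    calls: Iterable[BoundaryCall], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("position\tstrand\tkind\tscore\n")
        for b in calls:
            fh.write(f"{b.position}\t{b.strand}\t{b.kind}\t{b.score:g}\n")


def read_boundaries_tsv(path: str | os.PathLike) -> list[BoundaryCall]:
    calls: list[BoundaryCall] = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for need in ("position", "strand", "kind"):
            if need not in idx:
                raise InputError(f"{path}: missing column {need!r}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                calls.append(
                    BoundaryCall(
                        position=int(parts[idx["position"]]),
                        strand=parts[idx["strand"]],
                        kind=parts[idx["kind"]],
                        score=float(parts[idx["score"]]) if "score" in idx else 0.0,
                    )
                )
            except (ValueError, IndexError) as exc:
                raise InputError(f"{path}:{lineno}: bad boundary row") from exc
    return sorted(calls, key=lambda b: (b.position, b.strand, b.kind))


def write_evidence_tsv(
    evidence: Iterable[JunctionEvidence], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("from_gene\tto_gene\tdetected\n")
        for ev in evidence:
            fh.write(f"{ev.from_gene}\t{ev.to_gene}\t{ev.detected}\n")


def read_evidence_tsv(path: str | os.PathLike) -> list[JunctionEvidence]:
    rows: list[JunctionEvidence] = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header[:3] != ["from_gene", "to_gene", "detected"]:
            raise InputError(f"{path}: expected from_gene/to_gene/detected header")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            f, t, d = line.rstrip("\n").split("\t")[:3]
            if d not in ("True", "False", "true", "false", "1", "0"):
                raise InputError(f"{path}:{lineno}: detected must be boolean")
            rows.append(JunctionEvidence(f, t, d in ("True", "true", "1")))
    return rows
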