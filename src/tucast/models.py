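"""Core domain types.

Coordinates follow GFF3 conventions: 1-based, inclusive on both ends.
Strand is ``+`` or ``-``. Conversions to 0-based half-open array indexing
are centralized in :mod:`tucast.trackio`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InputError

STRANDS = ("+", "-")

#: cistron-class names by gene count; larger units fall back to "<n>-cistron"
CISTRON_CLASSES = {
    1: "mono",
    2: "bi",
    3: "tri",
    4: "tetra",
    5: "penta",
    6: "hexa",
    7: "hepta",
    8: "octa",
}


def cistron_class(n_genes: int) -> str:
    return CISTRON_CLASSES.get(n_genes, f"{n_genes}-cistron")


@dataclass(frozen=True)
class GeneModel:
    """One annotated CDS: contig, strand and 1-based inclusive coordinates."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InputError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in STRANDS:
            raise InputError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def tx_start(self) -> int:
        """First transcribed base (5' end in transcription direction)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tx_end(self) -> int:
        """Last transcribed base (3' end in transcription direction)."""
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class OverlapLink:
    """An adjacent same-strand gene pair whose coding sequences overlap.

    ``upstream_gene``/``downstream_gene`` are given in transcription order
    (on the minus strand the upstream gene is the rightmost one).
    ``junction_seq`` is the sense-strand span covering both the upstream
    stop codon and the downstream start codon; for the canonical 4-bp
    overlap this is the ATGA/GTGA tetranucleotide. ``codon_shared_nt`` is
    the number of nucleotides the two codons share (0 for overlaps > 5 bp).
    ``coupled`` marks the pair as translationally coupled.
    """

    upstream_gene: str
    downstream_gene: str
    overlap_bp: int
    junction_seq: str
    coupled: bool
    codon_shared_nt: int = 0

    def __post_init__(self) -> None:
        if self.overlap_bp < 1:
            raise InputError("OverlapLink requires a positive overlap")


@dataclass(frozen=True)
class BoundaryCall:
    """A transcript boundary: step-up (TSS) or step-down (TTS) in coverage.

    ``score`` is the fold change of downstream over upstream mean depth,
    evaluated in transcription direction.
    """

    position: int
    strand: str
    kind: str  # "TSS" or "TTS"
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("TSS", "TTS"):
            raise InputError(f"unknown boundary kind {self.kind!r}")
        if self.strand not in STRANDS:
            raise InputError(f"bad boundary strand {self.strand!r}")


@dataclass(frozen=True)
class TranscriptionUnit:
    """An ordered, strand-consistent, contiguous run of co-transcribed genes."""

    tu_id: str
    genes: tuple[str, ...]  # transcription order
    strand: str
    cistron_class: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise InputError("empty transcription unit")
        if self.cistron_class == "":
            object.__setattr__(self, "cistron_class", cistron_class(len(self.genes)))


@dataclass(frozen=True)
class JunctionEvidence:
    """RT-PCR style evidence for one gene junction.

    ``detected=True`` means an upstream transcript was amplified from cDNA
    primed in the downstream gene, i.e. the two genes share a transcript.
    """

    from_gene: str
    to_gene: str
    detected: bool


@dataclass
class DEConfig:
    """Thresholds for two-library differential calls."""

    lfc_threshold: float = 1.0
    p_threshold: float = 0.005
    method: str = "z"  # "z" (pooled two-proportion) or "fisher" (exact)


@dataclass
class DEResult:
    gene_id: str
    count_orig: float
    count_mut: float
    log2fc: float  # nan when undefined (a zero count, no pseudocount policy)
    p_value: float
    q_value: float = float("nan")
    status: str = "not_significant"  # up | down | not_significant | excluded


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a simulated dataset."""

    true_tus: list[list[str]] = field(default_factory=list)  # transcription order
    true_status: dict[str, str] = field(default_factory=dict)  # up|down|unchanged
    true_boundaries: list[BoundaryCall] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)
    true_fpkm: dict[str, float] = field(default_factory=dict)
    deleted_gene: str | None = None
    cluster_genes: list[str] = field(default_factory=list)
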