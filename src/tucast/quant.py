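"""Expression quantification: FPKM, per-gene coverage, condition alignment.

FPKM (fragments per kilobase of transcript per million mapped fragments) is
the within-sample expression measure used for transcription-unit merging
decisions; between-condition fold changes are computed on readcounts in
:mod:`tucast.de`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError
from .models import GeneModel
from .trackio import StrandedCoverage, to0


def compute_fpkm(count, gene_length_bp, total_fragments):
    """FPKM = count * 1e9 / (gene_length_bp * total_fragments).

    Accepts scalars or numpy arrays. Counts may be non-integral (normalized
    counts are allowed). Non-positive lengths or totals are a domain error.
    """
    count = np.asarray(count, dtype=float)
    length = np.asarray(gene_length_bp, dtype=float)
    total = np.asarray(total_fragments, dtype=float)
    if np.any(length <= 0):
        raise InputError("gene length must be positive")
    if np.any(total <= 0):
        raise InputError("total fragment count must be positive")
    if np.any(count < 0):
        raise InputError("counts must be non-negative")
    out = count * 1e9 / (length * total)
    return float(out) if out.ndim == 0 else out


def per_gene_mean_coverage(coverage: StrandedCoverage, gene: GeneModel) -> float:
    """Arithmetic mean depth over the gene body on the gene's strand."""
    track = coverage.get(gene.contig, gene.strand)
    if gene.end > track.size:
        raise InputError(
            f"gene {gene.gene_id} extends past track end ({gene.end} > {track.size})"
        )
    s0, e0 = to0(gene.start, gene.end)
    return float(track[s0:e0].mean())


def fpkm_from_coverage(
    coverage: StrandedCoverage, genes: list[GeneModel]
) -> dict[str, float]:
    """Mean depth per gene, used as an FPKM-scale expression proxy."""
    return {g.gene_id: per_gene_mean_coverage(coverage, g) for g in genes}


def align_conditions(
    matrix_a: pd.DataFrame, matrix_b: pd.DataFrame
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Inner-join two gene-indexed count matrices.

    Each input must be indexed by gene id (or have a ``gene_id`` column).
    Returns the joined table plus the gene ids present only in ``a`` and only
    in ``b``. Duplicate gene ids are an error.
    """
    frames = []
    for name, m in (("a", matrix_a), ("b", matrix_b)):
        m = m.set_index("gene_id") if "gene_id" in m.columns else m
        if m.index.has_duplicates:
            dups = m.index[m.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate gene ids in matrix {name}: {dups[:5]}")
        frames.append(m)
    a, b = frames
    joined = a.join(b, how="inner", lsuffix="_a", rsuffix="_b")
    only_a = sorted(set(a.index) - set(b.index))
    only_b = sorted(set(b.index) - set(a.index))
    return joined, only_a, only_b
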