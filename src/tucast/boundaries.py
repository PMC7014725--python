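"""Transcript-boundary calling from stranded coverage.

A transcription start site (TSS) appears as a step-up and a termination site
(TTS) as a step-down of per-base depth, read in transcription direction.
The detector compares mean depth in two flanking windows at every position;
it is a deliberately simple stand-in for dedicated bacterial transcript
assemblers, sufficient for clean step-like tracks. External boundary calls
(e.g. from such an assembler) can be supplied as TSV instead via
:func:`tucast.trackio.read_boundaries_tsv`.
"""

from __future__ import annotations

import warnings

import numpy as np

from .models import BoundaryCall
from .trackio import StrandedCoverage

#: defaults recover all fixture-scale steps; pseudodepth avoids divide-by-zero
DEFAULT_WINDOW_BP = 25
DEFAULT_MIN_RATIO = 3.0
DEFAULT_MIN_DEPTH = 5.0
PSEUDODEPTH = 0.5


def _scan(arr: np.ndarray, window: int, min_ratio: float, min_depth: float):
    """Yield (pos0, kind, score) on a forward-transcribed track.

    ``pos0`` is the 0-based index of the first base of the downstream window;
    a TSS is reported at that base, a TTS at the base before it.
    """
    L = arr.size
    prefix = np.concatenate(([0.0], np.cumsum(arr)))
    p = np.arange(window, L - window + 1)
    up = (prefix[p] - prefix[p - window]) / window
    down = (prefix[p + window] - prefix[p]) / window

    tss_score = down / (up + PSEUDODEPTH)
    tss_mask = (down >= min_depth) & (tss_score >= min_ratio)
    tts_score = up / (down + PSEUDODEPTH)
    tts_mask = (up >= min_depth) & (tts_score >= min_ratio)
    for pos0, score in zip(p[tss_mask], tss_score[tss_mask]):
        yield int(pos0), "TSS", float(score)
    for pos0, score in zip(p[tts_mask], tts_score[tts_mask]):
        yield int(pos0), "TTS", float(score)


def _merge_nearby(calls: list[BoundaryCall], window: int) -> list[BoundaryCall]:
    """Collapse calls of the same kind/strand within ``window`` bp, keeping the
    maximum-score call of each cluster."""
    merged: list[BoundaryCall] = []
    for key in sorted({(c.strand, c.kind) for c in calls}):
        group = sorted(
            (c for c in calls if (c.strand, c.kind) == key),
            key=lambda c: c.position,
        )
        cluster: list[BoundaryCall] = []
        for c in group:
            if cluster and c.position - cluster[-1].position > window:
                merged.append(max(cluster, key=lambda x: x.score))
                cluster = []
            cluster.append(c)
        if cluster:
            merged.append(max(cluster, key=lambda x: x.score))
    return sorted(merged, key=lambda c: (c.position, c.strand, c.kind))


def detect_boundaries(
    coverage: StrandedCoverage,
    window_bp: int = DEFAULT_WINDOW_BP,
    min_ratio: float = DEFAULT_MIN_RATIO,
    min_depth: float = DEFAULT_MIN_DEPTH,
) -> dict[str, list[BoundaryCall]]:
    """Call TSS/TTS per contig from step changes in stranded coverage.

    On the plus strand a TSS at 1-based position p means mean depth over
    [p, p+window) is >= ``min_depth`` and >= ``min_ratio`` times the mean over
    [p-window, p); a TTS is the symmetric step-down. The minus strand is
    evaluated on the reversed track so that both kinds are defined in
    transcription direction. Calls of one kind within ``window_bp`` of each
    other are merged keeping the maximum-score call.
    """
    if window_bp < 1 or min_ratio <= 1:
        raise ValueError("window_bp must be >= 1 and min_ratio > 1")
    out: dict[str, list[BoundaryCall]] = {}
    for contig in coverage.contigs():
        L = coverage.length(contig)
        calls: list[BoundaryCall] = []
        if L < 2 * window_bp:
            warnings.warn(
                f"track {contig!r} shorter than 2*window ({L} < {2 * window_bp}); "
                "no boundaries called",
                stacklevel=2,
            )
            out[contig] = []
            continue
        for strand in ("+", "-"):
            arr = coverage.get(contig, strand)
            work = arr if strand == "+" else arr[::-1]
            for pos0, kind, score in _scan(work, window_bp, min_ratio, min_depth):
                if kind == "TSS":
                    pos1 = pos0 + 1  # first base of the high window
                else:
                    pos1 = pos0  # last base of the high window
                if strand == "-":
                    pos1 = L - pos1 + 1
                calls.append(BoundaryCall(pos1, strand, kind, score))
        out[contig] = _merge_nearby(calls, window_bp)
    return out
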