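"""Homology search: ungapped placements of known matures on both strands.

The alignment model is a full-length, ungapped placement of the mature on
the transcript (forward) or on its reverse complement, keeping placements
with Hamming distance <= ``max_mismatch``. Score = 2*matches - 3*mismatches
(megablast-like rewards) and the expectation follows the Karlin-Altschul
form E = K*m*n*exp(-lambda*S). The decisive filter is the mismatch cap,
which is exact; score/E-value constants are configurable.

Candidate placements are generated by a pigeonhole seed index: the mature is
split into ``max_mismatch + 1`` contiguous chunks, at least one of which
must occur exactly in any placement within the mismatch budget, so the
result is identical to a naive scan of every offset on both strands.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .seqio import KnownMiRNA, Transcript, revcomp

KARLIN_K = 0.71
KARLIN_LAMBDA = 1.33
MATCH_REWARD = 2
MISMATCH_PENALTY = 3


@dataclass(frozen=True)
class HomologyHit:
    mirna_id: str
    transcript_id: str
    start: int  # 0-based half-open on the + strand
    end: int
    strand: str  # "+" or "-"
    mismatches: int
    score: float
    e_value: float


def alignment_score(matches: int, mismatches: int) -> float:
    return MATCH_REWARD * matches - MISMATCH_PENALTY * mismatches


def expectation(score: float, m: int, n: int) -> float:
    return KARLIN_K * m * n * math.exp(-KARLIN_LAMBDA * score)


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _chunks(mature: str, n_chunks: int) -> list[tuple[int, str]]:
    length = len(mature)
    base = length // n_chunks
    out = []
    pos = 0
    for i in range(n_chunks):
        size = base + (1 if i < length % n_chunks else 0)
        out.append((pos, mature[pos : pos + size]))
        pos += size
    return out


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    return index


def _scan_one_strand(
    seq: str, mature: str, max_mismatch: int, indexes: dict[int, dict[str, list[int]]]
) -> set[int]:
    """Candidate start offsets of the mature on ``seq`` (one strand)."""
    length = len(mature)
    starts: set[int] = set()
    for off, chunk in _chunks(mature, max_mismatch + 1):
        k = len(chunk)
        if k not in indexes:
            indexes[k] = _kmer_index(seq, k)
        for pos in indexes[k].get(chunk, ()):
            start = pos - off
            if 0 <= start <= len(seq) - length:
                starts.add(start)
    return {
        s for s in starts if _hamming(seq[s : s + length], mature) <= max_mismatch
    }


def find_hits(
    transcript: Transcript,
    reference: Sequence[KnownMiRNA],
    max_mismatch: int = 2,
) -> list[HomologyHit]:
    """All placements of each reference mature on both strands of a transcript.

    Minus-strand hits carry + strand coordinates of the matched interval.
    """
    if not reference:
        raise ValueError("empty reference set")
    seq = transcript.sequence
    rc = revcomp(seq)
    n = len(seq)
    fwd_idx: dict[int, dict[str, list[int]]] = {}
    rev_idx: dict[int, dict[str, list[int]]] = {}
    hits: list[HomologyHit] = []
    for ref in reference:
        mature = ref.mature
        length = len(mature)
        if length > n:
            continue
        for strand, s, idx in (("+", seq, fwd_idx), ("-", rc, rev_idx)):
            for start in _scan_one_strand(s, mature, max_mismatch, idx):
                mm = _hamming(s[start : start + length], mature)
                score = alignment_score(length - mm, mm)
                if strand == "+":
                    plus_start = start
                else:
                    plus_start = n - start - length
                hits.append(
                    HomologyHit(
                        mirna_id=ref.id,
                        transcript_id=transcript.id,
                        start=plus_start,
                        end=plus_start + length,
                        strand=strand,
                        mismatches=mm,
                        score=score,
                        e_value=expectation(score, length, n),
                    )
                )
    hits.sort(key=lambda h: (h.transcript_id, h.start, h.strand, h.mirna_id))
    return hits


def find_hits_many(
    transcripts: Iterable[Transcript],
    reference: Sequence[KnownMiRNA],
    max_mismatch: int = 2,
    *,
    skip_n: bool = True,
) -> list[HomologyHit]:
    """Hits over a whole transcript set; N-containing transcripts skipped by default."""
    hits: list[HomologyHit] = []
    for t in transcripts:
        if skip_n and t.has_n:
            continue
        hits.extend(find_hits(t, reference, max_mismatch))
    return hits


def filter_hits(
    hits: Iterable[HomologyHit],
    e_cut: float = 1e-2,
    score_cut: float = 32.0,
) -> list[HomologyHit]:
    """Keep hits with e_value < e_cut OR score > score_cut (strict bounds)."""
    return [h for h in hits if h.e_value < e_cut or h.score > score_cut]
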