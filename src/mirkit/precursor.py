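"""Candidate precursor windows around homology hits, and fragment merging."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .homology import HomologyHit
from .seqio import Transcript, revcomp

WINDOW_MIN_LEN = 50
WINDOW_MAX_LEN = 600


@dataclass(frozen=True)
class CandidateWindow:
    """A strand-resolved precursor window; the mature reads 5'->3' within it."""

    transcript_id: str
    strand: str
    win_start: int  # 0-based half-open on the + strand
    win_end: int
    sequence: str
    mature_offset: int  # offset of the mature within `sequence`
    mature_length: int

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def mature(self) -> str:
        return self.sequence[self.mature_offset : self.mature_offset + self.mature_length]


def extract_windows(
    transcript: Transcript,
    hit: HomologyHit,
    flank_min: int = 20,
    flank_max: int = 280,
    step: int = 20,
) -> list[CandidateWindow]:
    """Grid of candidate windows around a hit, clipped and deduplicated.

    Every (left, right) flank pair on the grid yields a window; minus-strand
    hits are resolved so the returned sequence is the reverse complement of
    the + strand slice and the mature reads 5'->3'.
    """
    n = transcript.length
    if not (0 <= hit.start < hit.end <= n):
        raise ValueError(f"hit [{hit.start},{hit.end}) outside transcript {transcript.id}")
    mlen = hit.end - hit.start
    flanks = range(flank_min, flank_max + 1, step)
    seen: set[tuple[int, int]] = set()
    windows: list[CandidateWindow] = []
    for left in flanks:
        for right in flanks:
            if hit.strand == "+":
                ws = max(0, hit.start - left)
                we = min(n, hit.end + right)
            else:  # the 5' flank of the hairpin lies 3' of the hit on + coords
                ws = max(0, hit.start - right)
                we = min(n, hit.end + left)
            if (ws, we) in seen:
                continue
            seen.add((ws, we))
            if not (WINDOW_MIN_LEN <= we - ws <= WINDOW_MAX_LEN):
                continue
            plus_seq = transcript.sequence[ws:we]
            if hit.strand == "+":
                seq = plus_seq
                offset = hit.start - ws
            else:
                seq = revcomp(plus_seq)
                offset = we - hit.end
            windows.append(
                CandidateWindow(
                    transcript_id=transcript.id,
                    strand=hit.strand,
                    win_start=ws,
                    win_end=we,
                    sequence=seq,
                    mature_offset=offset,
                    mature_length=mlen,
                )
            )
    return windows


@dataclass(frozen=True)
class MergeResult:
    sequences: tuple[Transcript, ...]
    merged: bool
    warning: str = ""


def merge_overlapping(
    fragments: Sequence[Transcript],
    guide_offsets: Sequence[int],
    min_overlap: int = 20,
) -> MergeResult:
    """Merge transcript fragments that overlap on a shared guide alignment.

    ``guide_offsets[i]`` is the offset of fragment i on the guide precursor.
    Fragments whose projected intervals overlap by >= ``min_overlap`` and
    agree exactly over the overlap are spliced; any disagreement aborts the
    merge for that pair. Chains merge associatively.
    """
    if len(fragments) < 2:
        raise ValueError("need at least 2 fragments to merge")
    if len(guide_offsets) != len(fragments):
        raise ValueError("one guide offset per fragment required")
    items = sorted(
        zip(guide_offsets, fragments), key=lambda p: (p[0], p[1].id)
    )
    merged_any = False
    warning = ""
    out: list[tuple[int, Transcript]] = [items[0]]
    counter = 0
    for off, frag in items[1:]:
        cur_off, cur = out[-1]
        overlap = cur_off + cur.length - off
        if overlap >= min_overlap and overlap <= min(cur.length, frag.length):
            if cur.sequence[off - cur_off :] == frag.sequence[:overlap]:
                counter += 1
                out[-1] = (
                    cur_off,
                    Transcript(
                        id=f"{cur.id}+{frag.id}",
                        sequence=cur.sequence + frag.sequence[overlap:],
                    ),
                )
                merged_any = True
                continue
            warning = "overlap disagreement; pair left unmerged"
        out.append((off, frag))
    if not merged_any and not warning:
        warning = "no overlapping pair"
    return MergeResult(
        sequences=tuple(t for _, t in out), merged=merged_any, warning=warning if not merged_any else ""
    )
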