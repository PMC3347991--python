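"""Target-site scanning with an additive penalizing score, plus cleavage
mapping and alignment rendering.

Scoring (per miRNA position, 1-based from the miRNA 5' end): Watson-Crick
pair 0, G:U wobble 0.5, mismatch 1.0, gap 2.0; penalties are doubled inside
the seed region (positions 2-7). At most one bulge (``max_gaps = 1``) on
either strand. Sites scoring <= the cut are putative targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .seqio import Transcript

WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}
SEED_RANGE = (2, 7)  # 1-based, inclusive
GAP_PENALTY = 2.0
MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5
SEED_MULTIPLIER = 2.0
DEFAULT_SCORE_CUT = 3.0
MAX_GAPS = 1

# An alignment is a tuple of columns (mirna_pos | None, site_index | None),
# ordered by ascending miRNA position; site indices are relative to the site
# and descend with miRNA position (the duplex is antiparallel).
Columns = tuple[tuple[Optional[int], Optional[int]], ...]


@dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    transcript_id: str
    site_start: int  # 0-based half-open on the transcript
    site_end: int
    score: float
    columns: Columns
    site_seq: str
    mirna_seq: str
    cleavage_pos: Optional[int] = None  # transcript position 5' of the cut bond
    cleavage_error: bool = False


def _seed_mult(pos: int) -> float:
    return SEED_MULTIPLIER if SEED_RANGE[0] <= pos <= SEED_RANGE[1] else 1.0


def _pair_penalty(m: str, t: str) -> float:
    if (m, t) in WC:
        return 0.0
    if (m, t) in WOBBLE:
        return WOBBLE_PENALTY
    return MISMATCH_PENALTY


def _alignments(mirna_len: int, site_len: int) -> Iterable[Columns]:
    """All <=1-gap antiparallel alignments of a miRNA onto a site."""
    L, Ls = mirna_len, site_len
    if Ls == L:
        yield tuple((p, L - p) for p in range(1, L + 1))
    elif Ls == L - 1:
        for g in range(1, L + 1):  # miRNA position g faces a target gap
            yield tuple(
                (p, None) if p == g else (p, L - 1 - p if p < g else L - p)
                for p in range(1, L + 1)
            )
    elif Ls == L + 1:
        for b in range(0, L + 1):  # site index b is bulged
            aligned = [i for i in range(L, -1, -1) if i != b]
            cols = [(p, aligned[p - 1]) for p in range(1, L + 1)]
            cols.append((None, b))
            yield tuple(cols)
    else:
        raise ValueError(
            f"site length {Ls} not within {MAX_GAPS} of miRNA length {L}"
        )


def _score_columns(mirna: str, site: str, columns: Columns) -> float:
    total = 0.0
    for p, idx in columns:
        if p is not None and idx is not None:
            total += _pair_penalty(mirna[p - 1], site[idx]) * _seed_mult(p)
        elif idx is None:  # gap opposite miRNA position p
            total += GAP_PENALTY * _seed_mult(p)
        else:  # bulged target nucleotide at site index idx
            p_after = sum(1 for q, i in columns if i is not None and i > idx) + 1
            total += GAP_PENALTY * _seed_mult(p_after)
    return total


def score_duplex(
    mirna: str, site: str, site_gapped: Columns | None = None
) -> float:
    """Minimum penalizing score of the miRNA against a candidate site.

    ``site_gapped`` pins a specific alignment; otherwise all placements of
    at most one gap are tried.
    """
    if site_gapped is not None:
        return _score_columns(mirna, site, site_gapped)
    return min(
        _score_columns(mirna, site, cols)
        for cols in _alignments(len(mirna), len(site))
    )


def _best_alignment(mirna: str, site: str) -> tuple[float, Columns]:
    best: tuple[float, int] | None = None
    best_cols: Columns = ()
    for rank, cols in enumerate(_alignments(len(mirna), len(site))):
        s = _score_columns(mirna, site, cols)
        if best is None or (s, rank) < best:
            best = (s, rank)
            best_cols = cols
    assert best is not None
    return best[0], best_cols


def predict_cleavage(site: TargetSite, mirna: str) -> Optional[int]:
    """Transcript coordinate of the bond between the target nucleotides
    pairing miRNA positions 10 and 11 (``None`` with an error flag if a gap
    interrupts those positions)."""
    idx = {p: i for p, i in site.columns if p is not None}
    if 10 not in idx or 11 not in idx or idx[10] is None or idx[11] is None:
        return None
    return site.site_start + idx[11]


def _with_cleavage(site: TargetSite, mirna: str) -> TargetSite:
    from dataclasses import replace

    pos = predict_cleavage(site, mirna)
    return replace(site, cleavage_pos=pos, cleavage_error=pos is None)


def scan_targets(
    mirna_id: str,
    mirna: str,
    transcripts: Sequence[Transcript],
    score_cut: float = DEFAULT_SCORE_CUT,
    max_gaps: int = MAX_GAPS,
) -> list[TargetSite]:
    """Every window scoring <= ``score_cut``, overlapping windows collapsed
    to the minimum-score placement, sorted by (score, transcript, start)."""
    L = len(mirna)
    found: list[TargetSite] = []
    for t in transcripts:
        seq = t.sequence
        candidates: list[TargetSite] = []
        for ls in range(L - max_gaps, L + max_gaps + 1):
            if ls < 1:
                continue
            for start in range(0, len(seq) - ls + 1):
                site = seq[start : start + ls]
                score, cols = _best_alignment(mirna, site)
                if score <= score_cut:
                    candidates.append(
                        TargetSite(
                            mirna_id=mirna_id,
                            transcript_id=t.id,
                            site_start=start,
                            site_end=start + ls,
                            score=score,
                            columns=cols,
                            site_seq=site,
                            mirna_seq=mirna,
                        )
                    )
        # collapse overlaps: best score wins, ties to the leftmost placement
        candidates.sort(key=lambda s: (s.score, s.site_start, s.site_end))
        kept: list[TargetSite] = []
        for cand in candidates:
            if all(
                cand.site_end <= k.site_start or cand.site_start >= k.site_end
                for k in kept
            ):
                kept.append(cand)
        found.extend(_with_cleavage(s, mirna) for s in kept)
    found.sort(key=lambda s: (s.score, s.transcript_id, s.site_start))
    return found


def render_alignment(site: TargetSite, mirna: str | None = None) -> str:
    """Three-line text block: target 5'->3', match symbols, miRNA 3'->5'.

    ``|`` marks Watson-Crick pairs, ``o`` G:U wobbles, space mismatches and
    gap columns; gaps appear as ``-`` in the sequence lines.
    """
    mirna = mirna or site.mirna_seq
    # order columns left-to-right by ascending transcript coordinate
    def sort_key(col):
        p, idx = col
        if idx is not None:
            return float(idx)
        # miRNA-gap column sits between its neighbours on the site
        left = [i for q, i in site.columns if i is not None and q > p]
        return max(left) + 0.5 if left else -0.5

    ordered = sorted(site.columns, key=sort_key)
    top, mid, bot = [], [], []
    for p, idx in ordered:
        if p is not None and idx is not None:
            m, t = mirna[p - 1], site.site_seq[idx]
            top.append(t)
            bot.append(m)
            pen = _pair_penalty(m, t)
            mid.append("|" if pen == 0 else "o" if pen == WOBBLE_PENALTY else " ")
        elif idx is None:
            top.append("-")
            bot.append(mirna[p - 1])
            mid.append(" ")
        else:
            top.append(site.site_seq[idx])
            bot.append("-")
            mid.append(" ")
    return (
        f"5' {''.join(top)} 3'\n"
        f"   {''.join(mid)}\n"
        f"3' {''.join(bot)} 5'"
    )
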