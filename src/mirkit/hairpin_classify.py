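"""Precursor criteria: duplex location, MFE/AMFE/MFEI/A+U filters, selection.

Thresholds follow the literal reading of the filtering rules: MFE <= -15
kcal/mol (inclusive), MFEI > 0.5 (strict), 30 <= A+U% <= 70 (inclusive on
both ends), mature:star duplex mismatches < 6 (strict), and the mature must
sit entirely in one arm of the hairpin. A+U% is computed on the precursor
window, not the mature. G:U counts as a structural pair in the duplex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .folding import SecondaryStructure
from .precursor import CandidateWindow
from .seqio import au_percent

STAR_OVERHANG = 2  # Dicer-style 2-nt 3' overhang on the star


@dataclass(frozen=True)
class CriteriaConfig:
    mfe_max: float = -15.0  # inclusive upper bound on MFE
    mfei_min: float = 0.5  # strict lower bound
    au_min_pct: float = 30.0  # inclusive
    au_max_pct: float = 70.0  # inclusive
    max_duplex_mismatch: int = 6  # exclusive bound
    require_single_arm: bool = True

    def __post_init__(self) -> None:
        if self.au_min_pct >= self.au_max_pct:
            raise ValueError("au_min_pct must be < au_max_pct")


@dataclass(frozen=True)
class DuplexInfo:
    arm: str  # "5p" or "3p"
    star: str
    duplex_mismatches: int
    star_span: tuple[int, int]  # [lo, hi] within the window, pre-overhang


@dataclass(frozen=True)
class PrecursorCandidate:
    window: CandidateWindow
    structure: SecondaryStructure
    arm: str  # "5p", "3p" or "" when rejected
    star: str
    duplex_mismatches: int
    mfe: float
    amfe: float
    mfei: float
    au_pct: float
    pass_flags: dict = field(default_factory=dict)
    reasons: tuple[str, ...] = ()

    @property
    def passes(self) -> bool:
        return bool(self.pass_flags) and all(self.pass_flags.values())

    @property
    def mature_length(self) -> int:
        return self.window.mature_length


def compute_mfei(mfe: float, length: int, au_pct: float) -> tuple[float, float]:
    """AMFE = |MFE|*100/length; MFEI = AMFE / (100 - A+U%) i.e. AMFE / G+C%."""
    if mfe > 0:
        raise ValueError("mfe must be <= 0")
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 <= au_pct < 100:
        raise ValueError("A+U% of 100 leaves MFEI undefined")
    amfe = abs(mfe) * 100.0 / length
    return amfe, amfe / (100.0 - au_pct)


def locate_duplex(
    window: CandidateWindow, structure: SecondaryStructure
) -> DuplexInfo | str:
    """Locate the mature:star duplex, or return a rejection reason string.

    Rejections: ``no-stem`` (mature entirely unpaired / open chain),
    ``loop-overlap`` (a mature position lies in a terminal loop) and
    ``both-arms`` (mature pairs on both sides, i.e. straddles the loop).
    G:U counts as a structural pair. A 1x1 internal loop contributes one
    mismatch; bulged nucleotides on either strand count 1 each.
    """
    pairs = structure.pairs
    m0 = window.mature_offset
    m1 = m0 + window.mature_length  # half-open
    mature_positions = range(m0, m1)
    if structure.is_open_chain:
        return "no-stem"
    # terminal (hairpin) loops: unpaired spans directly closed by a pair
    for i, j in enumerate(pairs):
        if j > i and all(pairs[k] == -1 for k in range(i + 1, j)):
            if m0 <= j - 1 and m1 - 1 >= i + 1 and not (m1 <= i + 1 or m0 >= j):
                # any overlap between [m0, m1) and loop (i, j) interior
                if max(m0, i + 1) < min(m1, j):
                    return "loop-overlap"
    partners = [pairs[k] for k in mature_positions if pairs[k] != -1]
    if not partners:
        return "no-stem"
    if any(p < m0 for p in partners) and any(p >= m1 for p in partners):
        return "both-arms"
    arm = "5p" if partners[0] >= m1 else "3p"
    lo, hi = min(partners), max(partners)
    # mismatch count: frayed mature ends count 1 per nucleotide; each
    # interior gap counts max(mature-side, star-side) unpaired nucleotides,
    # so a 1x1 loop is 1 mismatch and bulges count per bulged nucleotide
    paired_positions = [k for k in mature_positions if pairs[k] != -1]
    mismatches = (paired_positions[0] - m0) + (m1 - 1 - paired_positions[-1])
    for p, q in zip(paired_positions, paired_positions[1:]):
        mismatches += max(q - p - 1, abs(pairs[p] - pairs[q]) - 1)
    star_end = min(len(window.sequence), hi + 1 + STAR_OVERHANG)
    star = window.sequence[lo:star_end]
    return DuplexInfo(
        arm=arm, star=star, duplex_mismatches=mismatches, star_span=(lo, hi)
    )


def evaluate(
    window: CandidateWindow,
    structure: SecondaryStructure,
    cfg: CriteriaConfig | None = None,
) -> PrecursorCandidate:
    """Apply every precursor criterion; failures are data, not errors."""
    cfg = cfg or CriteriaConfig()
    au = au_percent(window.sequence)
    mfe = structure.mfe
    amfe, mfei = compute_mfei(min(mfe, 0.0), window.length, au)
    duplex = locate_duplex(window, structure)
    rejected = isinstance(duplex, str)
    flags = {
        "mfe": mfe <= cfg.mfe_max,
        "mfei": mfei > cfg.mfei_min,
        "au": cfg.au_min_pct <= au <= cfg.au_max_pct,
        "duplex": (not rejected)
        and duplex.duplex_mismatches < cfg.max_duplex_mismatch,
        "arm": (not rejected) or not cfg.require_single_arm,
    }
    reasons = tuple(
        ([duplex] if rejected else [])
        + [name for name, ok in flags.items() if not ok]
    )
    return PrecursorCandidate(
        window=window,
        structure=structure,
        arm="" if rejected else duplex.arm,
        star="" if rejected else duplex.star,
        duplex_mismatches=-1 if rejected else duplex.duplex_mismatches,
        mfe=mfe,
        amfe=amfe,
        mfei=mfei,
        au_pct=au,
        pass_flags=flags,
        reasons=reasons,
    )


def select_best(
    candidates: Sequence[PrecursorCandidate],
) -> Optional[PrecursorCandidate]:
    """Best passing candidate: highest MFEI, then shorter window, then
    smaller start coordinate; ``None`` if nothing passes."""
    passing = [c for c in candidates if c.passes]
    if not passing:
        return None
    return min(
        passing, key=lambda c: (-c.mfei, c.window.length, c.window.win_start)
    )
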