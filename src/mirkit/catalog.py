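"""Family assignment, member naming and catalog summary statistics."""

from __future__ import annotations

import math
import re
import string
from collections import Counter
from dataclasses import dataclass, replace
from importlib import resources
from typing import Sequence

import numpy as np

from .seqio import KnownMiRNA, family_from_id


@dataclass(frozen=True)
class MiRNARecord:
    """One catalog entry: a mature miRNA with its precursor-level statistics."""

    name: str
    family: str
    mature: str
    arm: str  # "5p" or "3p"
    au_pct: float  # A+U% of the precursor window
    mfe: float  # folding energy of the precursor, kcal/mol
    mfei: float
    precursor_id: str = ""
    locus_start: int = 0

    @property
    def length(self) -> int:
        return len(self.mature)

    @property
    def five_prime_u(self) -> bool:
        return self.mature.startswith("U")


@dataclass(frozen=True)
class CatalogSummary:
    n_mirnas: int
    n_families: int
    length_histogram: dict[int, int]
    pct_by_length: dict[int, int]
    five_prime_u_count: int
    five_prime_u_pct: int
    mfei_mean: float
    mfei_sd: float
    mfei_min: float
    mfei_max: float
    family_sizes: dict[str, int]


def load_builtin_catalog() -> list[MiRNARecord]:
    """The packaged 34-record conserved-miRNA catalog fixture."""
    text = resources.files("mirkit.data").joinpath("conserved_mirnas.tsv").read_text()
    lines = text.strip().splitlines()
    header = lines[0].split("\t")
    out = []
    for line in lines[1:]:
        vals = dict(zip(header, line.split("\t")))
        out.append(
            MiRNARecord(
                name=vals["name"],
                family=family_from_id(vals["name"]),
                mature=vals["mature"],
                arm=vals["arm"],
                au_pct=float(vals["au_pct"]),
                mfe=float(vals["mfe"]),
                mfei=float(vals["mfei"]),
                precursor_id=vals["name"] + "_precursor",
            )
        )
    return out


def builtin_reference() -> list[KnownMiRNA]:
    """The builtin catalog recast as a homology reference set."""
    return [
        KnownMiRNA(id=r.name, mature=r.mature, family=r.family)
        for r in load_builtin_catalog()
    ]


def _ungapped_distance(a: str, b: str) -> tuple[int, int]:
    """(min mismatches, longest exact run at the best offset).

    The shorter sequence slides along the longer; overhanging positions of
    either sequence count as mismatches, so length differences are penalized.
    """
    if len(a) > len(b):
        a, b = b, a
    la, lb = len(a), len(b)
    best = (la + lb, 0)
    for off in range(-(la - 1), lb):
        overlap_start = max(0, off)
        overlap_end = min(lb, off + la)
        overlap = overlap_end - overlap_start
        mism = (la - overlap) + (lb - overlap)
        run = best_run = 0
        for k in range(overlap_start, overlap_end):
            if b[k] == a[k - off]:
                run += 1
                best_run = max(best_run, run)
            else:
                mism += 1
                run = 0
        if (mism, -best_run) < (best[0], -best[1]):
            best = (mism, best_run)
    return best


def assign_family(
    mature: str,
    reference: Sequence[KnownMiRNA],
    max_family_mismatch: int = 4,
) -> str:
    """Family of the closest reference mature, or ``"unassigned"``.

    Ties break toward the reference with the longest exact match run, then
    the lexicographically smallest family name.
    """
    if not reference:
        raise ValueError("empty reference set")
    scored = []
    for ref in reference:
        mism, run = _ungapped_distance(mature, ref.mature)
        scored.append((mism, -run, ref.family))
    mism, _, family = min(scored)
    return family if mism <= max_family_mismatch else "unassigned"


_FAM_NUM_RE = re.compile(r"MIR(\d+)")


def _letter_suffix(i: int) -> str:
    # a..z, then aa, ab, ...
    out = ""
    while True:
        out = string.ascii_lowercase[i % 26] + out
        i = i // 26 - 1
        if i < 0:
            return out


def name_members(
    records: Sequence[MiRNARecord], prefix: str = "pde"
) -> list[MiRNARecord]:
    """Assign deterministic letter-suffixed names within each family.

    Members are ordered by (precursor transcript id, locus coordinate);
    single-member families get suffix "a" as well.
    """
    by_family: dict[str, list[MiRNARecord]] = {}
    for r in records:
        by_family.setdefault(r.family, []).append(r)
    renamed: dict[int, MiRNARecord] = {}
    for family, members in by_family.items():
        m = _FAM_NUM_RE.fullmatch(family)
        num = m.group(1) if m else family
        members = sorted(members, key=lambda r: (r.precursor_id, r.locus_start, r.mature))
        for i, rec in enumerate(members):
            renamed[id(rec)] = replace(
                rec, name=f"{prefix}-miR{num}{_letter_suffix(i)}"
            )
    return [renamed[id(r)] for r in records]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def summarize(records: Sequence[MiRNARecord]) -> CatalogSummary:
    """Headline statistics of a catalog: length histogram, 5'-U fraction,
    MFEI moments and family sizes. Percentages round half-up to integers."""
    if not records:
        raise ValueError("cannot summarize an empty catalog")
    n = len(records)
    hist = Counter(r.length for r in records)
    mfei = np.array([r.mfei for r in records], dtype=float)
    u_count = sum(1 for r in records if r.five_prime_u)
    fam = Counter(r.family for r in records)
    return CatalogSummary(
        n_mirnas=n,
        n_families=len(fam),
        length_histogram=dict(sorted(hist.items())),
        pct_by_length={
            k: _round_half_up(100.0 * v / n) for k, v in sorted(hist.items())
        },
        five_prime_u_count=u_count,
        five_prime_u_pct=_round_half_up(100.0 * u_count / n),
        mfei_mean=round(float(mfei.mean()), 2),
        mfei_sd=round(float(mfei.std(ddof=1)) if n > 1 else 0.0, 2),
        mfei_min=float(mfei.min()),
        mfei_max=float(mfei.max()),
        family_sizes=dict(sorted(fam.items())),
    )
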