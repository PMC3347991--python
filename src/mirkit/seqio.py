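"""Sequence I/O and alphabet handling.

All sequences are held internally as RNA (``U`` canonical, ``T`` accepted on
input only) and all internal coordinates are 0-based half-open on the plus
strand of the stored transcript.  Conversions to 1-based inclusive
coordinates happen only at the GFF3/report boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .catalog import MiRNARecord
    from .hairpin_classify import PrecursorCandidate

RNA_ALPHABET = frozenset("ACGU")
_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")

CATALOG_COLUMNS = (
    "name",
    "family",
    "mature",
    "arm",
    "length",
    "au_pct",
    "mfe",
    "mfei",
    "precursor_id",
)


class EmptyInputError(ValueError):
    """Raised when an input file contains no records."""


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside the RNA alphabet."""


def normalize(seq: str, *, allow_n: bool = False) -> str:
    """Uppercase a nucleotide string and convert DNA ``T`` to RNA ``U``.

    Raises :class:`AlphabetError` for anything outside ``{A,C,G,T,U}``
    (plus ``N`` when ``allow_n`` is set).
    """
    out = seq.upper().replace("T", "U")
    allowed = RNA_ALPHABET | ({"N"} if allow_n else set())
    bad = set(out) - allowed
    if bad:
        raise AlphabetError(f"invalid nucleotide(s) {sorted(bad)} in sequence")
    return out


def revcomp(seq: str) -> str:
    """Reverse complement in RNA space."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_percent(seq: str) -> float:
    return 100.0 * sum(1 for b in seq if b in "GC") / len(seq)


def au_percent(seq: str) -> float:
    return 100.0 * sum(1 for b in seq if b in "AU") / len(seq)


@dataclass(frozen=True)
class Transcript:
    """An assembled mRNA/contig; coordinates on its plus strand."""

    id: str
    sequence: str
    has_n: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class KnownMiRNA:
    """A reference mature miRNA with its family label."""

    id: str
    mature: str
    family: str = ""
    species_tag: str = ""

    def __post_init__(self) -> None:
        if not 18 <= len(self.mature) <= 26:
            raise ValueError(
                f"mature length {len(self.mature)} outside [18, 26] for {self.id}"
            )
        if not self.family:
            object.__setattr__(self, "family", family_from_id(self.id))
        if not self.species_tag:
            m = re.match(r"^([a-z]{2,4})-", self.id)
            object.__setattr__(self, "species_tag", m.group(1) if m else "")


_FAMILY_RE = re.compile(r"^(?:[a-zA-Z]{2,4}-)?(?:miR|MIR)-?(\d+)[a-z]*(?:[-.].*)?$")


def family_from_id(mirna_id: str) -> str:
    """Parse a family label (``MIR482``) from a gene name (``pde-miR482d``).

    Drops the species prefix, normalizes the ``miR``/``MIR`` casing and
    removes trailing letter suffixes.
    """
    m = _FAMILY_RE.match(mirna_id)
    if not m:
        raise ValueError(f"cannot parse miRNA family from id {mirna_id!r}")
    return f"MIR{m.group(1)}"


def read_fasta(
    path: str | Path, alphabet: str = "rna", *, allow_n: bool = False
) -> list[Transcript]:
    """Read a FASTA file into :class:`Transcript` objects.

    ``alphabet`` may be ``"rna"`` or ``"dna"``; either way sequences are
    normalized to RNA. Records containing ``N`` are flagged (``has_n``) and
    only accepted when ``allow_n`` is set.
    """
    if alphabet not in ("rna", "dna"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    out: list[Transcript] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = normalize(str(rec.seq), allow_n=allow_n)
        out.append(Transcript(id=rec.id, sequence=seq, has_n="N" in seq))
    return out


def read_reference(path: str | Path) -> list[KnownMiRNA]:
    """Read a reference mature-miRNA FASTA; family labels come from the ids."""
    transcripts = read_fasta(path, alphabet="rna")
    return [KnownMiRNA(id=t.id, mature=t.sequence) for t in transcripts]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def _fmt(value) -> str:
    # repr round-trips floats bit-exactly
    return repr(value) if isinstance(value, float) else str(value)


def write_catalog(records: Sequence["MiRNARecord"], path: str | Path) -> None:
    """Write catalog records to TSV (one row per record, header first)."""
    names = [r.name for r in records]
    if len(set(names)) != len(names):
        raise ValueError("duplicate record names in catalog")
    with open(path, "w") as fh:
        fh.write("\t".join(CATALOG_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(_fmt(getattr(r, col)) for col in CATALOG_COLUMNS) + "\n"
            )


def read_catalog(path: str | Path) -> list["MiRNARecord"]:
    """Read a TSV written by :func:`write_catalog` back into records."""
    from .catalog import MiRNARecord

    out: list[MiRNARecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != CATALOG_COLUMNS:
            raise ValueError(f"unexpected catalog header {header!r}")
        for line in fh:
            vals = dict(zip(CATALOG_COLUMNS, line.rstrip("\n").split("\t")))
            out.append(
                MiRNARecord(
                    name=vals["name"],
                    family=vals["family"],
                    mature=vals["mature"],
                    arm=vals["arm"],
                    au_pct=float(vals["au_pct"]),
                    mfe=float(vals["mfe"]),
                    mfei=float(vals["mfei"]),
                    precursor_id=vals["precursor_id"],
                )
            )
    return out


def write_gff3(
    candidates: Sequence["PrecursorCandidate"],
    transcript_lengths: dict[str, int],
    path: str | Path,
    *,
    source: str = "mirkit",
) -> None:
    """Write precursor loci as GFF3 (1-based inclusive coordinates).

    Emits one ``miRNA_primary_transcript`` feature per candidate with a child
    ``miRNA`` feature for the mature placement.
    """
    lines = ["##gff-version 3"]
    for i, cand in enumerate(candidates, start=1):
        w = cand.window
        tlen = transcript_lengths.get(w.transcript_id)
        if tlen is None:
            raise ValueError(f"unknown transcript {w.transcript_id!r}")
        if not (0 <= w.win_start < w.win_end <= tlen):
            raise ValueError(
                f"window [{w.win_start},{w.win_end}) outside transcript "
                f"{w.transcript_id} (length {tlen})"
            )
        pid = f"precursor{i}"
        lines.append(
            "\t".join(
                [
                    w.transcript_id,
                    source,
                    "miRNA_primary_transcript",
                    str(w.win_start + 1),
                    str(w.win_end),
                    ".",
                    w.strand,
                    ".",
                    f"ID={pid}",
                ]
            )
        )
        # mature coordinates back on the + strand of the transcript
        mlen = cand.mature_length
        if w.strand == "+":
            m_start = w.win_start + w.mature_offset
        else:
            m_start = w.win_end - w.mature_offset - mlen
        lines.append(
            "\t".join(
                [
                    w.transcript_id,
                    source,
                    "miRNA",
                    str(m_start + 1),
                    str(m_start + mlen),
                    ".",
                    w.strand,
                    ".",
                    f"ID={pid}.mature;Parent={pid}",
                ]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
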