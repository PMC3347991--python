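"""Synthetic inputs with planted ground truth for every pipeline stage.

Everything is deterministic under a fixed seed. Background composition is
uniform over {A,C,G,U} by default with a configurable A+U bias so planted
hairpins dominate the folding signal; decoys keep the mature sequence intact
inside a shuffled, non-hairpin context.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .seqio import Transcript, revcomp
from . import targets as _targets

BASES = np.array(list("ACGU"))

# a base that can pair (canonically or via G:U) with neither key base
_NONPAIRING = {"A": "C", "C": "A", "G": "A", "U": "C"}

LOOP_PATTERN = "CAACAACAACAACAAC"  # A/C only: cannot pair with itself


@dataclass(frozen=True)
class PlantedHairpin:
    mature: str
    duplex_mismatches: int = 0
    loop_len: int = 8
    flank_len: int = 30
    strand: str = "+"


@dataclass(frozen=True)
class SimulationSpec:
    seed: int = 0
    n_transcripts: int = 30
    transcript_len: tuple[int, int] = (220, 360)
    planted: tuple[PlantedHairpin, ...] = ()
    n_decoys: int = 20
    target_specs: tuple[tuple[str, float], ...] = ()
    ct_specs: tuple[tuple[str, float, float, int], ...] = ()
    au_bias: float = 0.5  # probability mass on {A, U}


def default_spec(seed: int = 0) -> SimulationSpec:
    """The default desk-scale simulation: 20 plantings with 0-3 duplex
    mismatches (including minus-strand ones) and 20 shuffled-context decoys."""
    from .catalog import load_builtin_catalog

    matures: list[str] = []
    for rec in load_builtin_catalog():
        if rec.mature not in matures:
            matures.append(rec.mature)
    matures = matures[:20]
    planted = tuple(
        PlantedHairpin(
            mature=m,
            duplex_mismatches=[0, 1, 2, 3][i % 4],
            strand="-" if i % 3 == 2 else "+",
        )
        for i, m in enumerate(matures)
    )
    target_specs = tuple(
        (m, s) for m, s in zip(matures, [0.0, 0.5, 1.0, 2.0, 3.0])
    )
    ct_specs = tuple(
        (f"gene{i + 1}", fold, 0.1, 3)
        for i, fold in enumerate([9.0, 4.0, 2.5, 2.2, 3.0, 2.1, 5.0, 1.0, 0.5, 1.5])
    )
    return SimulationSpec(
        seed=seed,
        planted=planted,
        target_specs=target_specs,
        ct_specs=ct_specs,
    )


def make_hairpin(mature: str, duplex_mismatches: int = 0, loop_len: int = 8) -> str:
    """A precursor ``mature + loop + star`` with exactly the requested number
    of non-pairing duplex positions.

    The star is the reverse complement of the mature with a centered block
    of ``duplex_mismatches`` non-pairing substitutions (an m x m internal
    loop, which the duplex counter scores as m). ``duplex_mismatches = 0``
    pairs every mature position.
    """
    L = len(mature)
    if not 18 <= L <= 24:
        raise ValueError(f"mature length {L} outside [18, 24]")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3")
    if duplex_mismatches < 0 or duplex_mismatches >= L:
        raise ValueError(f"cannot plant {duplex_mismatches} mismatches in a {L}-nt mature")
    star = list(revcomp(mature))
    if duplex_mismatches > L - 10:
        raise ValueError("too many duplex mismatches for this mature length")
    # one contiguous block at the mature's center: an m x m internal loop
    # flanked by >= 5-bp stems, which the MFE fold reliably reproduces;
    # substituted bases are A/C only, so no pair can form inside the loop
    block_start = (L - duplex_mismatches) // 2
    for p in range(block_start, block_start + duplex_mismatches):
        star[L - 1 - p] = _NONPAIRING[mature[p]]
    loop = (LOOP_PATTERN * ((loop_len // len(LOOP_PATTERN)) + 1))[:loop_len]
    return mature + loop + "".join(star)


def _random_seq(rng: np.random.Generator, length: int, au_bias: float = 0.5) -> str:
    p_au = au_bias / 2.0
    p_gc = (1.0 - au_bias) / 2.0
    return "".join(rng.choice(BASES, size=length, p=[p_au, p_gc, p_gc, p_au]))


def _shuffled_context(rng: np.random.Generator, context: str, mature: str) -> str:
    """Shuffle a hairpin context until it has no long complementary run to
    the mature (so the decoy cannot rebuild a passing duplex)."""
    rc = revcomp(mature)
    arr = np.array(list(context))
    for _ in range(200):
        rng.shuffle(arr)
        shuffled = "".join(arr)
        if not any(rc[i : i + 7] in shuffled for i in range(len(rc) - 6)):
            return shuffled
    raise RuntimeError("could not shuffle context free of complementary runs")


def _decoy_region_passes(seq: str, tid: str, m_start: int, mlen: int) -> bool:
    """True if any candidate window anchored at the planted mature would be
    accepted by the default precursor criteria (used to reject decoy
    placements whose random background happens to complete a hairpin)."""
    from .folding import fold_mfe
    from .hairpin_classify import evaluate, select_best
    from .homology import HomologyHit
    from .precursor import extract_windows

    t = Transcript(id=tid, sequence=seq)
    hit = HomologyHit(
        mirna_id="decoy-check",
        transcript_id=tid,
        start=m_start,
        end=m_start + mlen,
        strand="+",
        mismatches=0,
        score=0.0,
        e_value=0.0,
    )
    windows = extract_windows(t, hit)
    candidates = [evaluate(w, fold_mfe(w.sequence)) for w in windows]
    return select_best(candidates) is not None


def make_transcriptome(spec: SimulationSpec) -> tuple[list[Transcript], pd.DataFrame]:
    """Random transcripts with planted precursors and decoys, plus the truth
    table recording every planting.

    Decoy placements are verified: if the surrounding random background
    would itself complete a passing hairpin around the intact mature, the
    background is redrawn, so the truth labels stay correct."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.transcript_len
    transcripts: list[Transcript] = []
    truth_rows: list[dict] = []
    decoy_matures = [p.mature for p in spec.planted] or ["UUUGGUUUGAAGGGAGCUCUA"]
    n_total = len(spec.planted) + spec.n_decoys
    if spec.n_transcripts < n_total:
        n_total_transcripts = n_total
    else:
        n_total_transcripts = spec.n_transcripts
    inserts: list[tuple[str, dict]] = []
    for i, plant in enumerate(spec.planted):
        pre = make_hairpin(plant.mature, plant.duplex_mismatches, plant.loop_len)
        inserts.append(
            (
                pre,
                {
                    "kind": "planting",
                    "mature": plant.mature,
                    "strand": plant.strand,
                    "duplex_mismatches": plant.duplex_mismatches,
                },
            )
        )
    for i in range(spec.n_decoys):
        mature = decoy_matures[i % len(decoy_matures)]
        pre = make_hairpin(mature, 0)
        context = _shuffled_context(rng, pre[len(mature) :], mature)
        inserts.append(
            (
                mature + context,
                {
                    "kind": "decoy",
                    "mature": mature,
                    "strand": "+",
                    "duplex_mismatches": -1,
                },
            )
        )
    for idx in range(n_total_transcripts):
        tid = f"synth{idx + 1}"
        tlen = int(rng.integers(lo, hi + 1))
        background = _random_seq(rng, tlen, spec.au_bias)
        if idx < len(inserts):
            element, meta = inserts[idx]
            if meta["strand"] == "-":
                embedded = revcomp(element)
            else:
                embedded = element
            if len(embedded) + 60 > tlen:
                tlen = len(embedded) + 60
                background = _random_seq(rng, tlen, spec.au_bias)
            mlen = len(meta["mature"])
            for _attempt in range(30):
                pos = int(rng.integers(30, tlen - len(embedded) - 29))
                seq = background[:pos] + embedded + background[pos + len(embedded) :]
                if meta["strand"] == "+":
                    m_start = pos  # mature leads the precursor
                else:
                    m_start = pos + len(embedded) - mlen
                if meta["kind"] != "decoy" or not _decoy_region_passes(
                    seq, tid, m_start, mlen
                ):
                    break
                background = _random_seq(rng, tlen, spec.au_bias)
            else:
                raise RuntimeError(f"could not place decoy in {tid}")
            truth_rows.append(
                {
                    "transcript_id": tid,
                    **meta,
                    "element_start": pos,
                    "element_end": pos + len(embedded),
                    "mature_start": m_start,
                    "mature_end": m_start + mlen,
                }
            )
            transcripts.append(Transcript(id=tid, sequence=seq))
        else:
            transcripts.append(Transcript(id=tid, sequence=background))
    truth = pd.DataFrame(truth_rows)
    return transcripts, truth


def _engineer_site(mature: str, intended: float) -> str:
    """A target site whose penalizing score is exactly ``intended``."""
    if intended < 0 or (intended * 2) % 1 != 0:
        raise ValueError(f"penalty {intended} unreachable under the scoring table")
    L = len(mature)
    site = list(revcomp(mature))  # site index i faces miRNA position L - i
    n_mismatch = int(intended)
    wobble = (intended % 1) == 0.5
    # edit positions outside the seed (2-7) and the cleavage span (10-11)
    candidates = [p for p in range(12, L) if p not in (L,)]
    candidates += [8, 9]
    used: list[int] = []
    if wobble:
        wp = next(
            (p for p in candidates if mature[p - 1] in "GU"), None
        )
        if wp is None:
            raise ValueError("no wobble-capable position outside the seed")
        site[L - wp] = "U" if mature[wp - 1] == "G" else "G"
        used.append(wp)
    mis = [p for p in candidates if p not in used][:n_mismatch]
    if len(mis) < n_mismatch:
        raise ValueError(f"penalty {intended} needs more editable positions")
    for p in mis:
        site[L - p] = _NONPAIRING[mature[p - 1]]
    out = "".join(site)
    got = _targets.score_duplex(mature, out)
    if got != intended:
        raise ValueError(f"engineered site scored {got}, wanted {intended}")
    return out


def make_target_transcripts(
    specs: Sequence[tuple[str, float]],
    seed: int = 0,
    transcript_len: int = 300,
) -> tuple[list[Transcript], pd.DataFrame]:
    """One transcript per (mature, intended penalty), each carrying exactly
    one engineered site; the truth table records placements and penalties."""
    rng = np.random.default_rng(seed)
    transcripts: list[Transcript] = []
    rows: list[dict] = []
    for i, (mature, intended) in enumerate(specs):
        site = _engineer_site(mature, intended)
        tid = f"target{i + 1}"
        background = _random_seq(rng, transcript_len)
        pos = int(rng.integers(30, transcript_len - len(site) - 29))
        seq = background[:pos] + site + background[pos + len(site) :]
        transcripts.append(Transcript(id=tid, sequence=seq))
        rows.append(
            {
                "transcript_id": tid,
                "mature": mature,
                "site_start": pos,
                "site_end": pos + len(site),
                "intended_score": intended,
            }
        )
    return transcripts, pd.DataFrame(rows)


def make_ct_table(
    ct_specs: Sequence[tuple[str, float, float, int]],
    seed: int = 0,
    *,
    reference_gene: str = "rRNA5S",
    calibrator_sample: str = "stem",
    test_sample: str = "needle",
) -> pd.DataFrame:
    """Ct observations whose ddCt structure implies the requested true folds.

    Each spec is (gene, true fold in the test sample, Gaussian Ct sd,
    replicates). The reference gene is constant across samples up to noise.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    max_reps = max((r for *_, r in ct_specs), default=3)
    for sample in (calibrator_sample, test_sample):
        for rep in range(1, max_reps + 1):
            rows.append(
                {
                    "gene": reference_gene,
                    "sample": sample,
                    "replicate": rep,
                    "ct": 15.0 + rng.normal(0.0, _ref_sd(ct_specs)),
                }
            )
    for gene, fold, sd, reps in ct_specs:
        if fold <= 0 or sd < 0:
            raise ValueError("fold must be > 0 and sd >= 0")
        baseline = float(rng.uniform(20.0, 28.0))
        for sample in (calibrator_sample, test_sample):
            shift = 0.0 if sample == calibrator_sample else -float(np.log2(fold))
            for rep in range(1, reps + 1):
                rows.append(
                    {
                        "gene": gene,
                        "sample": sample,
                        "replicate": rep,
                        "ct": baseline + shift + rng.normal(0.0, sd),
                    }
                )
    return pd.DataFrame(rows)


def _ref_sd(ct_specs: Sequence[tuple[str, float, float, int]]) -> float:
    sds = [sd for *_, sd, _ in ct_specs]
    return min(sds) if sds else 0.0
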