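import dataclasses

import pytest

from mirkit.folding import SecondaryStructure, fold_mfe, pairs_from_dotbracket
from mirkit.hairpin_classify import (
    CriteriaConfig,
    compute_mfei,
    evaluate,
    locate_duplex,
    select_best,
)
from mirkit.precursor import CandidateWindow
from mirkit.seqio import au_percent
from mirkit.synthetic_data import make_hairpin

MATURE = "UUUGGUUUGAAGGGAGCUCUA"


def _window(seq, mature_len=len(MATURE), offset=0):
    return CandidateWindow(
        transcript_id="t", strand="+", win_start=0, win_end=len(seq),
        sequence=seq, mature_offset=offset, mature_length=mature_len,
    )


def _structure(dotbracket, mfe=-30.0):
    return SecondaryStructure(
        dotbracket=dotbracket, mfe=mfe, pairs=pairs_from_dotbracket(dotbracket)
    )


def _hairpin_candidate(mm=0):
    seq = make_hairpin(MATURE, mm)
    return _window(seq), fold_mfe(seq)


class TestComputeMfei:
    def test_round_numbers(self):
        assert compute_mfei(-50.0, 100, 50.0) == (50.0, 1.0)

    def test_boundary_construction(self):
        amfe, mfei = compute_mfei(-15.0, 100, 70.0)
        assert (amfe, round(mfei, 2)) == (15.0, 0.50)

    def test_formula_oracle(self, rng):
        for _ in range(50):
            mfe = -float(rng.uniform(1, 200))
            length = int(rng.integers(50, 600))
            au = float(rng.uniform(0, 99))
            amfe, mfei = compute_mfei(mfe, length, au)
            assert amfe == pytest.approx(abs(mfe) * 100 / length)
            assert mfei == pytest.approx(amfe / (100 - au))

    def test_undefined_at_full_au(self):
        with pytest.raises(ValueError):
            compute_mfei(-10.0, 100, 100.0)


class TestLocateDuplex:
    def test_perfect_duplex(self):
        win, structure = _hairpin_candidate(0)
        d = locate_duplex(win, structure)
        assert not isinstance(d, str)
        assert d.arm == "5p"
        assert d.duplex_mismatches == 0
        # star span covers the full mature; overhang clipped at window end
        assert len(d.star) == len(MATURE)

    def test_star_two_nt_overhang_with_flank(self):
        core = make_hairpin(MATURE, 0)
        seq = "GCAUGCAUGC" + core + "GCAUGCAUGC"
        win = CandidateWindow(
            transcript_id="t", strand="+", win_start=0, win_end=len(seq),
            sequence=seq, mature_offset=10, mature_length=len(MATURE),
        )
        d = locate_duplex(win, fold_mfe(seq))
        assert not isinstance(d, str)
        assert d.duplex_mismatches == 0
        assert len(d.star) == len(MATURE) + 2

    def test_open_chain_rejected(self):
        seq = "A" * 60
        d = locate_duplex(_window(seq), _structure("." * 60, 0.0))
        assert d == "no-stem"

    def test_mature_straddling_loop_rejected(self):
        seq = make_hairpin(MATURE, 0)
        # place the "mature" across the terminal loop region
        win = CandidateWindow(
            transcript_id="t", strand="+", win_start=0, win_end=len(seq),
            sequence=seq, mature_offset=12, mature_length=21,
        )
        assert locate_duplex(win, fold_mfe(seq)) in ("loop-overlap", "both-arms")

    def test_internal_loop_counted(self):
        win, structure = _hairpin_candidate(2)
        d = locate_duplex(win, structure)
        assert d.duplex_mismatches == 2

    def test_three_prime_arm(self):
        # same hairpin, mature designated on the star side
        seq = make_hairpin(MATURE, 0)
        star_start = len(seq) - len(MATURE)
        win = CandidateWindow(
            transcript_id="t", strand="+", win_start=0, win_end=len(seq),
            sequence=seq, mature_offset=star_start, mature_length=len(MATURE),
        )
        d = locate_duplex(win, fold_mfe(seq))
        assert not isinstance(d, str)
        assert d.arm == "3p"


class TestEvaluateBoundaries:
    def _eval(self, mfe=None, cfg=None):
        win, structure = _hairpin_candidate(0)
        if mfe is not None:
            structure = dataclasses.replace(structure, mfe=mfe)
        return evaluate(win, structure, cfg)

    def test_passing_baseline(self):
        cand = self._eval()
        assert cand.passes, cand.reasons

    def test_mfe_boundary_inclusive(self):
        assert self._eval(mfe=-15.0).pass_flags["mfe"]
        cand = self._eval(mfe=-14.9)
        assert not cand.pass_flags["mfe"]
        assert "mfe" in cand.reasons

    def test_mfei_boundary_strict(self):
        win, structure = _hairpin_candidate(0)
        au = au_percent(win.sequence)
        # engineer MFEI == 0.5 exactly
        mfe = -0.5 * (100.0 - au) * win.length / 100.0
        cand = evaluate(win, dataclasses.replace(structure, mfe=mfe))
        assert cand.mfei == pytest.approx(0.5)
        assert not cand.pass_flags["mfei"]
        assert "mfei" in cand.reasons

    def test_au_boundaries_inclusive(self):
        # exact-A+U windows: 30% and 70% pass, just outside fails
        cases = [
            ("AU" * 15 + "GC" * 35, True),   # 30/100 = 30.0%
            ("AU" * 35 + "GC" * 15, True),   # 70.0%
            ("AU" * 14 + "GC" * 36, False),  # 28.0%
            ("AU" * 36 + "GC" * 14, False),  # 72.0%
        ]
        for seq, expected in cases:
            cand = evaluate(_window(seq), _structure("." * len(seq), 0.0))
            assert cand.pass_flags["au"] is expected, au_percent(seq)

    def test_duplex_mismatch_boundary_strict(self):
        cfg = CriteriaConfig(max_duplex_mismatch=2)
        win, structure = _hairpin_candidate(2)
        cand = evaluate(win, structure, cfg)
        assert cand.duplex_mismatches == 2
        assert not cand.pass_flags["duplex"]

    def test_amfe_mfei_invariants_conserved(self):
        win, structure = _hairpin_candidate(1)
        cand = evaluate(win, structure)
        assert cand.amfe == pytest.approx(abs(cand.mfe) * 100 / win.length)
        assert cand.mfei == pytest.approx(cand.amfe / (100 - cand.au_pct))

    def test_monotone_in_thresholds(self):
        base = CriteriaConfig()
        loosened = [
            CriteriaConfig(mfe_max=-10.0),
            CriteriaConfig(mfei_min=0.3),
            CriteriaConfig(au_min_pct=20.0),
            CriteriaConfig(au_max_pct=80.0),
            CriteriaConfig(max_duplex_mismatch=8),
        ]
        for mm in (0, 1, 2, 3, 4):
            win, structure = _hairpin_candidate(mm)
            if evaluate(win, structure, base).passes:
                for cfg in loosened:
                    assert evaluate(win, structure, cfg).passes


class TestSelectBest:
    def _passing(self, mm=0, mfei=None, length=None, start=0):
        win, structure = _hairpin_candidate(mm)
        cand = evaluate(win, structure)
        updates = {}
        if mfei is not None:
            updates["mfei"] = mfei
        if length is not None:
            updates["window"] = dataclasses.replace(
                cand.window,
                win_start=start,
                win_end=start + length,
                sequence=cand.window.sequence[:1] * length,
            )
        return dataclasses.replace(cand, **updates) if updates else cand

    def test_single_passing(self):
        cand = self._passing()
        assert select_best([cand]) is cand

    def test_highest_mfei_wins(self):
        a = self._passing(mfei=0.9)
        b = self._passing(mfei=1.1)
        assert select_best([a, b]) is b

    def test_tie_broken_by_length(self):
        a = self._passing(mfei=1.0, length=120)
        b = self._passing(mfei=1.0, length=90)
        assert select_best([a, b]) is b

    def test_none_when_nothing_passes(self):
        win, structure = _hairpin_candidate(0)
        failing = evaluate(win, dataclasses.replace(structure, mfe=-1.0))
        assert select_best([failing]) is None
        assert select_best([]) is None
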