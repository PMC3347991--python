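import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirkit.seqio import Transcript, revcomp
from mirkit.targets import (
    TargetSite,
    predict_cleavage,
    render_alignment,
    scan_targets,
    score_duplex,
)

from .conftest import random_rna

MIRNA = "UGAUUGAGCCGUGCCAAUAUC"  # 21 nt; 'G' at positions 2,6,8,11,13
L = len(MIRNA)


def _site_with(edits: dict[int, str]) -> str:
    """revcomp site with site-index -> base substitutions (ungapped)."""
    site = list(revcomp(MIRNA))
    for idx, base in edits.items():
        site[idx] = base
    return "".join(site)


class TestScoreDuplex:
    def test_perfect_complement_is_zero(self, catalog_records):
        for rec in catalog_records[:10]:
            assert score_duplex(rec.mature, revcomp(rec.mature)) == 0.0

    @given(st.text(alphabet="ACGU", min_size=18, max_size=24))
    @settings(max_examples=50, deadline=None)
    def test_identity_property(self, mirna):
        assert score_duplex(mirna, revcomp(mirna)) == 0.0

    def test_wobble_outside_seed(self):
        # miRNA position 11 ('G') opposite 'U' -> 0.5, undoubled
        assert score_duplex(MIRNA, _site_with({L - 11: "U"})) == 0.5

    def test_wobble_inside_seed_doubled(self):
        # position 5 is 'U'; pairing it with 'G' doubles to 1.0
        assert MIRNA[4] == "U"
        assert score_duplex(MIRNA, _site_with({L - 5: "G"})) == 1.0

    def test_mismatch_outside_seed(self):
        # position 12 is 'U'; 'C' opposite it pairs neither way
        assert score_duplex(MIRNA, _site_with({L - 12: "C"})) == 1.0

    def test_mismatch_inside_seed_doubled(self):
        assert score_duplex(MIRNA, _site_with({L - 4: "C"})) == 2.0

    def test_single_gap(self):
        site = list(revcomp(MIRNA))
        del site[L - 15]  # gap opposite miRNA position 15
        assert score_duplex(MIRNA, "".join(site)) == 2.0

    def test_mismatch_plus_gap_additive(self):
        site = list(_site_with({L - 12: "C"}))
        del site[L - 16]
        assert score_duplex(MIRNA, "".join(site)) == 3.0

    def test_length_beyond_gap_bound(self):
        with pytest.raises(ValueError):
            score_duplex(MIRNA, revcomp(MIRNA)[: L - 3])

    def test_flanking_invariance_via_scan(self, rng):
        # the same site scores identically wherever it sits
        site = _site_with({L - 12: "C"})
        for pos in (50, 120):
            bg = random_rna(rng, 300)
            t = Transcript(id="t", sequence=bg[:pos] + site + bg[pos + len(site) :])
            hits = [s for s in scan_targets("m", MIRNA, [t]) if s.site_start == pos]
            assert hits and hits[0].score == 1.0


class TestScanTargets:
    def _planted(self, rng, site, pos=100, n=300):
        bg = random_rna(rng, n)
        return Transcript(id="t", sequence=bg[:pos] + site + bg[pos + len(site) :])

    def test_planted_perfect_site(self, rng):
        t = self._planted(rng, revcomp(MIRNA))
        sites = scan_targets("m", MIRNA, [t])
        assert any(s.site_start == 100 and s.score == 0.0 for s in sites)

    def test_above_cut_absent(self, rng):
        from mirkit.synthetic_data import _engineer_site

        site = _engineer_site(MIRNA, 3.5)
        t = self._planted(rng, site)
        sites = scan_targets("m", MIRNA, [t])
        assert not any(s.site_start <= 100 < s.site_end for s in sites)

    def test_matches_naive_window_rescoring(self, rng):
        t = self._planted(rng, _site_with({L - 12: "C"}), pos=150, n=400)
        cut = 3.0
        naive = {}
        for ls in (L - 1, L, L + 1):
            for start in range(len(t.sequence) - ls + 1):
                s = score_duplex(MIRNA, t.sequence[start : start + ls])
                if s <= cut:
                    naive[(start, start + ls)] = s
        sites = scan_targets("m", MIRNA, [t], cut)
        # every reported site is a naive candidate with the same score
        for s in sites:
            assert naive[(s.site_start, s.site_end)] == s.score
        # reported sites are mutually non-overlapping
        spans = sorted((s.site_start, s.site_end) for s in sites)
        assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))
        # every naive candidate overlaps a reported site of <= its score
        for (st, en), sc in naive.items():
            assert any(
                s.site_start < en and st < s.site_end and s.score <= sc
                for s in sites
            )

    def test_lowering_cut_never_adds_sites(self, rng):
        t = self._planted(rng, _site_with({L - 12: "C"}))
        loose = {(s.site_start, s.site_end) for s in scan_targets("m", MIRNA, [t], 3.0)}
        tight = {(s.site_start, s.site_end) for s in scan_targets("m", MIRNA, [t], 1.0)}
        assert tight <= loose


class TestCleavage:
    def test_perfect_site_position(self, rng):
        t = TestScanTargets()._planted(rng, revcomp(MIRNA), pos=100)
        site = next(
            s for s in scan_targets("m", MIRNA, [t]) if s.site_start == 100
        )
        # bond between the nucleotides pairing miRNA positions 10 and 11
        assert site.cleavage_pos == 110
        assert not site.cleavage_error

    def test_translation_equivariance(self, rng):
        t = TestScanTargets()._planted(rng, revcomp(MIRNA), pos=105)
        site = next(
            s for s in scan_targets("m", MIRNA, [t]) if s.site_start == 105
        )
        assert site.cleavage_pos == 115

    def test_always_inside_site(self, rng):
        t = TestScanTargets()._planted(rng, revcomp(MIRNA))
        for s in scan_targets("m", MIRNA, [t]):
            if s.cleavage_pos is not None:
                assert s.site_start <= s.cleavage_pos < s.site_end

    def test_gap_at_cleavage_flags_error(self):
        # hand-built alignment with the gap opposite miRNA position 10
        cols = tuple(
            (p, None) if p == 10 else (p, (L - 1 - p) if p < 10 else (L - p))
            for p in range(1, L + 1)
        )
        site = TargetSite(
            mirna_id="m", transcript_id="t", site_start=0, site_end=L - 1,
            score=2.0, columns=cols, site_seq="A" * (L - 1), mirna_seq=MIRNA,
        )
        assert predict_cleavage(site, MIRNA) is None


class TestRenderAlignment:
    def _site(self, rng, raw_site):
        t = TestScanTargets()._planted(rng, raw_site)
        return next(s for s in scan_targets("m", MIRNA, [t]) if s.site_start == 100)

    def test_perfect_all_dashes(self, rng):
        block = render_alignment(self._site(rng, revcomp(MIRNA)))
        mid = block.splitlines()[1][3:]
        assert mid == "|" * L

    def test_single_wobble_circle(self, rng):
        block = render_alignment(self._site(rng, _site_with({L - 11: "U"})))
        mid = block.splitlines()[1][3:]
        assert mid.count("o") == 1
        assert mid.count("|") == L - 1

    def test_symbols_reproduce_score(self, rng):
        for edits in ({L - 11: "U"}, {L - 12: "C"}, {L - 12: "C", L - 11: "U"}):
            site = self._site(rng, _site_with(edits))
            mid = render_alignment(site).splitlines()[1][3:]
            total = 0.0
            for col, symbol in enumerate(mid):
                p = L - col  # leftmost column pairs the miRNA 3' end
                mult = 2.0 if 2 <= p <= 7 else 1.0
                total += {"|": 0.0, "o": 0.5, " ": 1.0}[symbol] * mult
            assert total == site.score
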