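"""Contiguous-match finder, local alignment, window scan and E-value."""

import math
import random

import pytest
from Bio.Align import substitution_matrices

from allerscreen.allergen_screen import (
    AlignmentResult,
    ScreenConfig,
    align_pair,
    estimate_evalue,
    find_contiguous_matches,
    screen,
    window_identity_scan,
)
from allerscreen.seq_core import SequenceError, SequenceRecord
from allerscreen.synthetic_data import make_allergen_panel, make_query_protein, PanelSpec

AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_matches(query, subject, k):
    """Independent oracle: every occurrence of every common substring,
    filtered to diagonal-maximal ones."""
    occ = set()
    for length in range(k, min(len(query), len(subject)) + 1):
        for qi in range(len(query) - length + 1):
            sub = query[qi : qi + length]
            if "X" in sub:
                continue
            start = 0
            while True:
                sj = subject.find(sub, start)
                if sj == -1:
                    break
                occ.add((qi + 1, sj + 1, length))
                start = sj + 1
    maximal = set()
    for qs, ss, ln in occ:
        contained = any(
            (qs2 - ss2 == qs - ss)
            and ln2 > ln
            and qs2 <= qs
            and qs2 + ln2 >= qs + ln
            for qs2, ss2, ln2 in occ
        )
        if not contained:
            maximal.add((qs, ss, ln))
    return maximal


class TestFindContiguousMatches:
    def test_planted_hexamer_recovered_with_coordinates(self):
        query = "A" * 46 + "GDGGVG" + "C" * 10  # GDGGVG at 47-52
        subject = "W" * 5 + "GDGGVG" + "Y" * 5
        (m,) = find_contiguous_matches(query, subject, 6)
        assert m.peptide == "GDGGVG"
        assert (m.query_start, m.query_end) == (47, 52)
        assert (m.subject_start, m.subject_end) == (6, 11)
        assert m.region_query() == "47GDGGVG52"

    def test_subthreshold_shared_5mer_yields_nothing(self):
        assert find_contiguous_matches("WWWGDGGVYYY", "KKGDGGVKK", 6) == []

    def test_identical_distinct_letters_collapse_to_one_maximal_match(self):
        # nested 6- and 7-mers of the common 8-mer are suppressed
        matches = find_contiguous_matches("ACDEFGHI", "ACDEFGHI", 6)
        assert len(matches) == 1
        assert matches[0].length == 8
        assert (matches[0].query_start, matches[0].query_end) == (1, 8)

    def test_k_larger_than_sequences_is_empty_not_error(self):
        assert find_contiguous_matches("ACDE", "ACDE", 6) == []

    def test_agrees_with_brute_force_oracle_on_random_pairs(self):
        rnd = random.Random(20240917)
        for _ in range(100):
            q = "".join(rnd.choice(AA[:8]) for _ in range(rnd.randint(6, 60)))
            s = "".join(rnd.choice(AA[:8]) for _ in range(rnd.randint(6, 60)))
            got = {
                (m.query_start, m.subject_start, m.length)
                for m in find_contiguous_matches(q, s, 6)
            }
            assert got == brute_force_matches(q, s, 6)

    def test_symmetry_swapping_roles_preserves_peptides(self):
        rnd = random.Random(7)
        q = "".join(rnd.choice(AA[:6]) for _ in range(50))
        s = "".join(rnd.choice(AA[:6]) for _ in range(50))
        fwd = find_contiguous_matches(q, s, 4)
        rev = find_contiguous_matches(s, q, 4)
        assert sorted(m.peptide for m in fwd) == sorted(m.peptide for m in rev)
        assert {(m.query_start, m.subject_start) for m in fwd} == {
            (m.subject_start, m.query_start) for m in rev
        }


def sw_linear_oracle(a, b, matrix_name, gap):
    """Quadratic Smith-Waterman DP with linear gap penalty (score only)."""
    mat = substitution_matrices.load(matrix_name)
    m, n = len(a), len(b)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            H[i][j] = max(
                0.0,
                H[i - 1][j - 1] + mat[a[i - 1], b[j - 1]],
                H[i - 1][j] - gap,
                H[i][j - 1] - gap,
            )
            best = max(best, H[i][j])
    return best


class TestAlignPair:
    def test_identical_sequences_full_identity(self):
        seq = "GDGGVGSIKTSHYHT"
        res = align_pair(seq, seq)
        assert res.percent_identity == 100.0
        assert res.query_span == (1, len(seq))
        assert res.subject_span == (1, len(seq))

    def test_textbook_instance_matches_dp_oracle(self):
        cfg = ScreenConfig(matrix="BLOSUM50", gap_open=0, gap_extend=8)
        res = align_pair("HEAGAWGHEE", "PAWHEAE", cfg)
        assert res.score == sw_linear_oracle("HEAGAWGHEE", "PAWHEAE", "BLOSUM50", 8)
        assert res.score == 28.0

    def test_random_pairs_match_dp_oracle(self):
        rnd = random.Random(11)
        cfg = ScreenConfig(matrix="BLOSUM62", gap_open=0, gap_extend=5)
        for _ in range(20):
            a = "".join(rnd.choice(AA) for _ in range(rnd.randint(10, 40)))
            b = "".join(rnd.choice(AA) for _ in range(rnd.randint(10, 40)))
            assert align_pair(a, b, cfg).score == sw_linear_oracle(a, b, "BLOSUM62", 5)

    def test_empty_subject_rejected(self):
        with pytest.raises(SequenceError):
            align_pair("GDGGVG", "")

    def test_unknown_matrix_rejected(self):
        with pytest.raises(ValueError, match="NOSUCH"):
            align_pair("GDGGVG", "GDGGVG", ScreenConfig(matrix="NOSUCH"))


def _fake_alignment(aligned_q, aligned_s):
    return AlignmentResult(
        aligned_query=aligned_q,
        aligned_subject=aligned_s,
        score=1.0,
        percent_identity=0.0,
        query_span=(1, len(aligned_q.replace("-", ""))),
        subject_span=(1, len(aligned_s.replace("-", ""))),
        evalue=1.0,
    )


class TestWindowIdentityScan:
    @pytest.mark.parametrize(
        "identities,expected_pct,expected_hit",
        [(29, 36.25, True), (28, 35.0, False)],
    )
    def test_regulatory_boundary_is_strict(self, identities, expected_pct, expected_hit):
        q = "W" * identities + "K" * (80 - identities)
        s = "W" * identities + "R" * (80 - identities)
        pct, hit, _ = window_identity_scan(_fake_alignment(q, s), 80, 35.0)
        assert pct == pytest.approx(expected_pct)
        assert hit is expected_hit

    def test_short_alignment_single_truncated_window(self):
        seq = "GDGGVGSIK" * 5  # 45 identical columns
        pct, hit, starts = window_identity_scan(_fake_alignment(seq, seq), 80, 35.0)
        assert pct == 100.0
        assert hit and starts == [1]

    def test_gap_columns_count_as_mismatches(self):
        pct, hit, _ = window_identity_scan(_fake_alignment("AC-DE", "ACFDE"), 80, 35.0)
        assert pct == pytest.approx(100 * 4 / 5)

    def test_hit_monotone_in_threshold(self):
        q = "W" * 30 + "K" * 70
        s = "W" * 30 + "R" * 70
        al = _fake_alignment(q, s)
        hits = [window_identity_scan(al, 80, thr)[1] for thr in (50, 37.5, 30, 20)]
        assert hits == sorted(hits)  # lowering threshold never removes a hit


class TestEstimateEvalue:
    def test_closed_form_oracle_value(self):
        cfg = ScreenConfig(evalue_k=0.13, evalue_lambda=0.32)
        # frozen from independent evaluation of K*m*n*exp(-lambda*S)
        assert estimate_evalue(50, 160, 160, cfg) == pytest.approx(
            3.745172e-4, rel=1e-5
        )

    def test_linear_in_subject_length(self):
        cfg = ScreenConfig()
        assert estimate_evalue(40, 100, 400, cfg) == pytest.approx(
            2 * estimate_evalue(40, 100, 200, cfg)
        )

    def test_score_shift_halves(self):
        cfg = ScreenConfig()
        shift = math.log(2) / cfg.evalue_lambda
        assert estimate_evalue(40 + shift, 100, 100, cfg) == pytest.approx(
            estimate_evalue(40, 100, 100, cfg) / 2
        )

    def test_nonpositive_lengths_rejected(self):
        with pytest.raises(ValueError):
            estimate_evalue(40, 0, 100)


@pytest.fixture(scope="module")
def screened(descriptor_table):
    query, _ = make_query_protein(seed=7)
    panel, truth = make_allergen_panel(PanelSpec.reference_default(seed=11))
    rows = screen(query, panel, descriptor_table=descriptor_table)
    return query, panel, truth, rows


class TestScreen:
    def test_one_row_per_panel_member_sorted_by_evalue(self, screened):
        _, panel, _, rows = screened
        assert len(rows) == len(panel)
        evs = [r.evalue for r in rows]
        assert evs == sorted(evs)

    def test_planted_motifs_set_kmer_flag(self, screened):
        _, _, truth, rows = screened
        by_id = {r.allergen_id: r for r in rows}
        for sid, motif, start, end in truth:
            row = by_id[sid]
            assert row.kmer_hit
            assert any(
                m.subject_start <= start and m.subject_end >= end
                for m in row.contiguous_matches
            ), f"{motif} at {start}-{end} not recovered for {sid}"

    def test_self_screen_is_maximal_hit(self, descriptor_table):
        query, _ = make_query_protein(seed=7)
        (row,) = screen(query, [query], descriptor_table=descriptor_table)
        assert row.full_identity == 100.0
        assert row.kmer_hit and row.window_hit
        assert row.pd_value == 0.0

    def test_unrelated_member_has_no_flags(self, descriptor_table):
        query = SequenceRecord(id="q", residues="ACDEFGHIKL" * 9)
        subject = SequenceRecord(id="s", residues="MNPQRSTVWY" * 9)
        (row,) = screen(query, [subject], descriptor_table=descriptor_table)
        assert not row.kmer_hit and not row.window_hit
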