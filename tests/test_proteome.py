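"""Pattern compilation, proteome scanning vs brute force, affinity filter."""

import pytest
from hypothesis import given, settings, strategies as st

from tcrspec import (
    AffinityPrediction,
    MissingPredictionError,
    Peptide,
    ValidationError,
    builtin_anchor_scorer,
    compile_pattern,
    filter_by_affinity,
    parse_pattern,
    scan_proteome,
)
from tcrspec.peptide import AMINO_ACIDS
from tcrspec.proteome import DegeneratePattern, ProteomeMatch, read_proteome
from tcrspec.simulate import gen_proteome
from tcrspec.xscan import RecognitionMotif


def brute_force_scan(pattern, proteome):
    """Independent oracle: check every window against the position sets."""
    n = len(pattern)
    out = []
    for pid, seq in sorted(proteome):
        for start0 in range(len(seq) - n + 1):
            window = seq[start0 : start0 + n]
            if all(r in s for r, s in zip(window, pattern.per_position_sets)):
                out.append((pid, start0 + 1, window))
    return out


def _pattern(*sets):
    return DegeneratePattern(
        per_position_sets=tuple(frozenset(s) for s in sets),
        pattern_text="-".join(
            "x" if len(s) == 20 else (s if len(s) == 1 else "[" + "".join(sorted(s)) + "]")
            for s in ("".join(sorted(x)) for x in sets)
        ),
    )


class TestCompilePattern:
    def test_syntax_mapping(self, nonamer):
        sets = [frozenset({c}) for c in nonamer.sequence]
        sets[0] = frozenset(AMINO_ACIDS)
        sets[1] = frozenset("ILV")
        motif = RecognitionMotif(cognate=nonamer, sets=tuple(sets))
        pattern = compile_pattern(motif)
        assert pattern.pattern_text == "x-[ILV]-G-A-V-G-V-G-K"

    def test_round_trip(self, decamer):
        sets = [frozenset({c}) for c in decamer.sequence]
        sets[0] = frozenset(AMINO_ACIDS)
        sets[4] = frozenset("AG")
        motif = RecognitionMotif(cognate=decamer, sets=tuple(sets))
        pattern = compile_pattern(motif)
        assert parse_pattern(pattern.pattern_text).per_position_sets == pattern.per_position_sets

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            DegeneratePattern(per_position_sets=(frozenset(),), pattern_text="?")

    def test_malformed_pattern_text_rejected(self):
        with pytest.raises(ValidationError):
            parse_pattern("V-[ILV-x")


class TestScanProteome:
    def test_planted_rab7b_like_coordinates(self):
        seq = "M" * 11 + "IIVGAIGVGK" + "W" * 20
        pattern = _pattern(
            "IV", "IV", "V", "G", "A", "IV", "G", "V", "G", "K"
        )
        matches = scan_proteome(pattern, [("RAB7B", seq)])
        assert [(m.start, m.end, m.matched_sequence) for m in matches] == [
            (12, 21, "IIVGAIGVGK")
        ]

    def test_overlapping_windows_each_reported(self):
        pattern = _pattern("V", AMINO_ACIDS)
        matches = scan_proteome(pattern, [("p1", "VVV")])
        assert [(m.start, m.end) for m in matches] == [(1, 2), (2, 3)]

    def test_non_canonical_residues_never_match(self):
        pattern = _pattern(AMINO_ACIDS, AMINO_ACIDS)
        matches = scan_proteome(pattern, [("p1", "AXUA")])
        assert [(m.start, m.end) for m in matches] == []

    def test_empty_proteome_is_empty_result(self):
        assert scan_proteome(_pattern("V"), []) == []

    def test_deterministic_order(self):
        pattern = _pattern("A")
        matches = scan_proteome(pattern, [("b", "AA"), ("a", "A")])
        assert [(m.protein_id, m.start) for m in matches] == [("a", 1), ("b", 1), ("b", 2)]

    def test_cognate_flagging(self, decamer):
        pattern = _pattern(*[{c} for c in decamer.sequence])
        matches = scan_proteome(
            pattern, [("KRAS", "MTEY" + decamer.sequence + "GAGG")], cognate=decamer.sequence
        )
        assert len(matches) == 1 and matches[0].is_cognate

    def test_matches_planted_and_equals_brute_force(self):
        pattern = _pattern("ILV", "ILV", "V", AMINO_ACIDS, "A", "V", "G", "V", "G", "KR")
        records, truth = gen_proteome(
            n_proteins=150, mean_length=300, pattern=pattern, n_planted=8, seed=21
        )
        fast = [(m.protein_id, m.start, m.matched_sequence) for m in scan_proteome(pattern, records)]
        assert fast == brute_force_scan(pattern, records)
        planted = {(p["protein_id"], p["start"]) for p in truth.parameters["planted"]}
        assert planted <= {(pid, start) for pid, start, _ in fast}

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_oracle_equivalence_on_random_instances(self, seed):
        """Property: vectorized scan equals the all-windows oracle."""
        import numpy as np

        rng = np.random.default_rng(seed)
        sets = [
            frozenset(rng.choice(list(AMINO_ACIDS), size=int(rng.integers(1, 6)), replace=False))
            for _ in range(int(rng.integers(2, 5)))
        ]
        # Short alphabet makes incidental matches frequent.
        records = [
            (f"r{i}", "".join(rng.choice(list("AVGKX"), size=int(rng.integers(0, 60)))))
            for i in range(5)
        ]
        pattern = _pattern(*["".join(s) for s in sets])
        fast = [(m.protein_id, m.start, m.matched_sequence) for m in scan_proteome(pattern, records)]
        assert fast == brute_force_scan(pattern, records)

    def test_stricter_motif_yields_subset_of_matches(self):
        loose = _pattern("ILVM", "AG", "KR")
        strict = _pattern("IL", "A", "K")
        records, _ = gen_proteome(n_proteins=50, mean_length=200, seed=3)
        loose_hits = {(m.protein_id, m.start) for m in scan_proteome(loose, records)}
        strict_hits = {(m.protein_id, m.start) for m in scan_proteome(strict, records)}
        assert strict_hits <= loose_hits

    def test_malformed_fasta_reports_line(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text("ACDEF\n>p1\nACDEF\n")
        with pytest.raises(ValidationError, match="line 1"):
            read_proteome(path)

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">p1\nACDEF\n>p1\nGHIKL\n")
        with pytest.raises(ValidationError, match="p1"):
            read_proteome(path)


def _match(seq, pid="p", start=1, cognate=False):
    return ProteomeMatch(
        protein_id=pid, start=start, end=start + len(seq) - 1, matched_sequence=seq, is_cognate=cognate
    )


def _pred(seq, nm, allele="A*11:01"):
    return AffinityPrediction(peptide=seq, allele=allele, predicted_ec50=nm)


class TestAffinityFilter:
    def test_500_boundary_is_inclusive(self):
        matches = [_match("AVIMAIGTTK"), _match("IIVGAIGVGK")]
        preds = [_pred("AVIMAIGTTK", 500.0), _pred("IIVGAIGVGK", 501.0)]
        cand = filter_by_affinity(matches, preds, allele="A*11:01")
        assert cand.candidate_peptides == ["AVIMAIGTTK"]
        assert len(cand.excluded) == 1
        assert cand.excluded[0].reason == "affinity"
        assert cand.excluded[0].match.matched_sequence == "IIVGAIGVGK"

    def test_cognate_flagged_not_candidate(self, decamer):
        matches = [_match(decamer.sequence, cognate=True), _match("IIVGAIGVGK")]
        cand = filter_by_affinity(matches, [_pred("IIVGAIGVGK", 10.0)], allele="A*11:01")
        assert [m.matched_sequence for m in cand.cognate_matches] == [decamer.sequence]
        assert cand.candidate_peptides == ["IIVGAIGVGK"]

    def test_missing_prediction_lists_peptides(self):
        with pytest.raises(MissingPredictionError, match="IIVGAIGVGK"):
            filter_by_affinity([_match("IIVGAIGVGK")], [], allele="A*11:01")

    def test_wrong_allele_prediction_does_not_count(self):
        preds = [_pred("IIVGAIGVGK", 10.0, allele="A*03:01")]
        with pytest.raises(MissingPredictionError):
            filter_by_affinity([_match("IIVGAIGVGK")], preds, allele="A*11:01")

    def test_idempotent(self):
        matches = [_match("AVIMAIGTTK"), _match("IIVGAIGVGK")]
        preds = [_pred("AVIMAIGTTK", 80.0), _pred("IIVGAIGVGK", 900.0)]
        once = filter_by_affinity(matches, preds, allele="A*11:01")
        again = filter_by_affinity([m for m, _ in once.candidates], preds, allele="A*11:01")
        assert [m.matched_sequence for m, _ in again.candidates] == [
            m.matched_sequence for m, _ in once.candidates
        ]
        assert again.excluded == ()


class TestBuiltinScorer:
    def test_basic_cterm_beats_acidic(self, decamer):
        good = builtin_anchor_scorer(decamer, "A*11:01")
        bad = builtin_anchor_scorer(Peptide("VVVGAVGVGD"), "A*11:01")
        assert good.predicted_ec50 < bad.predicted_ec50
        assert good.predictor_id == "builtin-anchor-pwm"

    def test_deterministic(self, nonamer):
        a = builtin_anchor_scorer(nonamer, "A*03:01")
        b = builtin_anchor_scorer(nonamer, "A*03:01")
        assert a == b

    def test_length_and_allele_contracts(self):
        with pytest.raises(ValidationError):
            builtin_anchor_scorer(Peptide("VVVGAVGVGKAA"), "A*11:01")  # 12-mer
        with pytest.raises(ValidationError):
            builtin_anchor_scorer(Peptide("VVGAVGVGK"), "B*07:02")
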