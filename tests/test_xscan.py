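"""Positional libraries, activity matrices, motif extraction, logos."""

import pytest
from hypothesis import given, settings, strategies as st

from tcrspec import (
    MissingDataError,
    Peptide,
    ValidationError,
    assemble_matrix,
    build_ala_gly_library,
    build_logo,
    build_xscan_library,
    extract_motif,
)
from tcrspec.peptide import AMINO_ACIDS
from tcrspec.simulate import gen_xscan
from tcrspec.xscan import RecognitionMotif, condition_id

peptides = st.text(alphabet=AMINO_ACIDS, min_size=8, max_size=12).map(Peptide)


def _full_readouts(library, value=70.0):
    return {e.condition_id: value for e in library.entries}


class TestLibraries:
    def test_xscan_sizes(self, decamer, nonamer):
        assert len(build_xscan_library(decamer)) == 190
        assert len(build_xscan_library(nonamer)) == 171

    @given(peptides)
    @settings(derandomize=True, max_examples=50)
    def test_xscan_entries_are_unique_single_substitutions(self, cognate):
        lib = build_xscan_library(cognate)
        assert len(lib) == 19 * len(cognate)
        seqs = {e.peptide.sequence for e in lib.entries}
        assert len(seqs) == len(lib)  # no duplicates
        for e in lib.entries:
            diffs = [
                i for i, (a, b) in enumerate(zip(cognate, e.peptide), start=1) if a != b
            ]
            assert diffs == [e.position]
            assert e.peptide[e.position - 1] == e.residue

    def test_ala_gly_convention(self, decamer):
        lib = build_ala_gly_library(decamer)
        assert len(lib) == 10
        by_pos = {e.position: e.residue for e in lib.entries}
        # VVVGAVGVGK: Ala everywhere, Gly at the P5 alanine
        assert by_pos[5] == "G"
        assert all(by_pos[p] == "A" for p in by_pos if p != 5)

    def test_ala_gly_all_alanine_cognate(self):
        lib = build_ala_gly_library(Peptide("AAAAAAAA"))
        assert all(e.residue == "G" for e in lib.entries)

    def test_non_canonical_cognate_rejected(self):
        with pytest.raises(ValidationError):
            Peptide("VVVGAXGVGK")

    def test_fasta_export(self, nonamer, tmp_path):
        lib = build_xscan_library(nonamer)
        path = tmp_path / "lib.fasta"
        lib.to_fasta(path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith(">P1_")
        assert len(lines) == 2 * 171


class TestAssembleMatrix:
    def test_cognate_cells_pinned_to_100(self, decamer):
        lib = build_xscan_library(decamer)
        matrix = assemble_matrix(lib, _full_readouts(lib, 30.0))
        for pos in range(1, 11):
            assert matrix.activity(pos, decamer[pos - 1]) == 100.0
        n_pinned = int((matrix.values == 100.0).sum().sum())
        assert n_pinned == 10

    def test_replicates_averaged_after_clipping(self, nonamer):
        lib = build_xscan_library(nonamer)
        readouts = _full_readouts(lib, 10.0)
        readouts[condition_id(4, "K")] = [60.0, 80.0]
        matrix = assemble_matrix(lib, readouts)
        assert matrix.activity(4, "K") == pytest.approx(70.0)

    def test_missing_entry_names_position_and_residue(self, nonamer):
        lib = build_xscan_library(nonamer)
        readouts = _full_readouts(lib)
        del readouts[condition_id(3, "W")]
        with pytest.raises(MissingDataError, match=r"\(3, 'W'\)"):
            assemble_matrix(lib, readouts)

    def test_matrix_tsv_round_trip(self, nonamer, tmp_path):
        from tcrspec.xscan import ActivityMatrix

        lib = build_xscan_library(nonamer)
        matrix = assemble_matrix(lib, _full_readouts(lib, 42.5))
        path = tmp_path / "matrix.tsv"
        matrix.to_tsv(path)
        back = ActivityMatrix.from_tsv(path, nonamer)
        assert (back.values == matrix.values).all().all()


class TestExtractMotif:
    def test_threshold_is_inclusive(self, nonamer):
        lib = build_xscan_library(nonamer)
        readouts = _full_readouts(lib, 10.0)
        readouts[condition_id(4, "K")] = 50.0  # exactly at the cutoff
        readouts[condition_id(4, "R")] = 49.999
        motif = extract_motif(assemble_matrix(lib, readouts))
        assert "K" in motif.sets[3]
        assert "R" not in motif.sets[3]

    def test_fully_tolerant_and_cognate_only_positions(self, decamer):
        lib = build_xscan_library(decamer)
        readouts = {}
        for e in lib.entries:
            readouts[e.condition_id] = 80.0 if e.position == 1 else 20.0
        motif = extract_motif(assemble_matrix(lib, readouts))
        assert motif.sets[0] == frozenset(AMINO_ACIDS)  # P1 fully tolerant
        assert motif.sets[5] == frozenset({"V"})  # P6 valine only

    def test_matrix_motif_consistency(self, nonamer):
        """A peptide matches iff every residue clears the cutoff at its position."""
        lib = build_xscan_library(nonamer)
        readouts = _full_readouts(lib, 10.0)
        readouts[condition_id(1, "I")] = 90.0
        matrix = assemble_matrix(lib, readouts)
        motif = extract_motif(matrix)
        assert motif.matches("IVGAVGVGK")
        assert motif.matches(nonamer.sequence)
        assert not motif.matches("LVGAVGVGK")
        for seq in ("IVGAVGVGK", "LVGAVGVGK"):
            expected = all(
                matrix.activity(p, r) >= motif.threshold
                for p, r in enumerate(seq, start=1)
            )
            assert motif.matches(seq) == expected

    @given(st.floats(1.0, 99.0), st.floats(1.0, 99.0))
    @settings(derandomize=True, max_examples=30)
    def test_raising_threshold_never_enlarges_sets(self, t1, t2):
        lo, hi = sorted((t1, t2))
        cognate = Peptide("VVGAVGVGK")
        readouts, _ = gen_xscan(
            _sample_motif(cognate), seed=5, tolerated_range=(0, 100), rejected_range=(0, 100)
        )
        lib = build_xscan_library(cognate)
        matrix = assemble_matrix(lib, readouts)
        m_lo = extract_motif(matrix, threshold=lo)
        m_hi = extract_motif(matrix, threshold=hi)
        for s_hi, s_lo in zip(m_hi.sets, m_lo.sets):
            assert s_hi <= s_lo

    def test_round_trip_from_latent_motif(self, nonamer):
        latent = _sample_motif(nonamer)
        readouts, _ = gen_xscan(latent, seed=11)
        lib = build_xscan_library(nonamer)
        recovered = extract_motif(assemble_matrix(lib, readouts), threshold=50.0)
        assert recovered.sets == latent.sets


def _sample_motif(cognate):
    sets = []
    for pos, cog in enumerate(cognate, start=1):
        if pos == 1:
            sets.append(frozenset(AMINO_ACIDS))
        elif pos == 5:
            sets.append(frozenset({cog}))
        else:
            sets.append(frozenset({cog, "I", "L"} if cog not in "IL" else {cog, "T"}))
    return RecognitionMotif(cognate=cognate, sets=tuple(sets))


class TestLogo:
    def test_stacks_filtered_sorted_and_scaled(self, nonamer):
        lib = build_xscan_library(nonamer)
        readouts = _full_readouts(lib, 10.0)
        readouts[condition_id(2, "I")] = 80.0
        readouts[condition_id(2, "L")] = 60.0
        readouts[condition_id(2, "M")] = 40.0  # below cutoff: absent
        logo = build_logo(assemble_matrix(lib, readouts))
        stack = logo.stacks[1]
        assert [r for r, _ in stack] == ["V", "I", "L"]
        assert [h for _, h in stack] == pytest.approx([1.0, 0.8, 0.6])

    def test_cognate_only_position_single_letter(self, nonamer):
        lib = build_xscan_library(nonamer)
        logo = build_logo(assemble_matrix(lib, _full_readouts(lib, 10.0)))
        for pos, stack in enumerate(logo.stacks):
            assert stack == ((nonamer[pos], 1.0),)

    def test_fully_tolerant_position_has_20_letters(self, nonamer):
        lib = build_xscan_library(nonamer)
        readouts = {
            e.condition_id: (90.0 if e.position == 1 else 10.0) for e in lib.entries
        }
        logo = build_logo(assemble_matrix(lib, readouts))
        assert len(logo.stacks[0]) == 20
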