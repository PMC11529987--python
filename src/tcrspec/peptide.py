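"""Peptide sequences over the 20 canonical amino acids."""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

#: Canonical one-letter codes, alphabetical.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AMINO_ACID_SET = frozenset(AMINO_ACIDS)

#: KRAS G12V decamer (KRAS 7-16 with V at the codon-12 position).
KRAS_G12V_DECAMER = "VVVGAVGVGK"
#: KRAS G12V nonamer (KRAS 8-16).
KRAS_G12V_NONAMER = "VVGAVGVGK"

MIN_LENGTH = 8
MAX_LENGTH = 21


@dataclass(frozen=True)
class Peptide:
    """A validated peptide: uppercase canonical residues, length 8-21.

    The length window covers class I epitopes (8-11-mers) and the longer
    synthetic vaccine peptides; anything outside it is almost certainly an
    input error in this context.
    """

    sequence: str
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        seq = self.sequence
        if not isinstance(seq, str) or not seq:
            raise ValidationError("peptide sequence must be a nonempty string")
        if seq != seq.upper():
            raise ValidationError(f"peptide sequence must be uppercase: {seq!r}")
        bad = sorted(set(seq) - AMINO_ACID_SET)
        if bad:
            raise ValidationError(
                f"non-canonical residue(s) {''.join(bad)!r} in peptide {seq!r}"
            )
        if not MIN_LENGTH <= len(seq) <= MAX_LENGTH:
            raise ValidationError(
                f"peptide length {len(seq)} outside [{MIN_LENGTH}, {MAX_LENGTH}]: {seq!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def __iter__(self):
        return iter(self.sequence)

    def __getitem__(self, i):
        return self.sequence[i]

    def __str__(self) -> str:
        return self.sequence
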