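"""Positional-scanning libraries, activity matrices, and recognition motifs.

An X-scan library substitutes each position of a cognate peptide with
every one of the other 19 amino acids (19 x n peptides for an n-mer);
an Ala/Gly library substitutes alanine at every position, with glycine
standing in wherever the cognate residue already is alanine. Reporter
readouts for the library, normalized to specific activity, populate a
position x residue ActivityMatrix (cognate cells pinned to 100 by the
anchors). Residues whose activity meets a threshold — 50% by default —
form the per-position allowed sets of the TCR recognition motif, and
the same thresholded activities (scaled to [0, 1]) give the letter
heights of an activity logo.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import MissingDataError, ValidationError
from .normalize import SpecificValue, aggregate_replicates
from .peptide import AMINO_ACIDS, Peptide

__all__ = [
    "LibraryEntry",
    "PositionalLibrary",
    "ActivityMatrix",
    "RecognitionMotif",
    "LogoModel",
    "build_xscan_library",
    "build_ala_gly_library",
    "assemble_matrix",
    "extract_motif",
    "build_logo",
    "condition_id",
]


def condition_id(position: int, residue: str) -> str:
    """Canonical condition name for a substitution, e.g. ``P4_K``."""
    return f"P{position}_{residue}"


@dataclass(frozen=True)
class LibraryEntry:
    position: int  # 1-based, P1 = N-terminus
    residue: str  # substituted amino acid
    peptide: Peptide

    @property
    def condition_id(self) -> str:
        return condition_id(self.position, self.residue)


@dataclass(frozen=True)
class PositionalLibrary:
    cognate: Peptide
    entries: tuple[LibraryEntry, ...]
    scheme: str  # "xscan" | "ala_gly"

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "condition_id": e.condition_id,
                    "position": e.position,
                    "residue": e.residue,
                    "peptide": e.peptide.sequence,
                }
                for e in self.entries
            ]
        )

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(f">{e.condition_id}\n{e.peptide.sequence}\n")


def _substitute(cognate: Peptide, position: int, residue: str) -> Peptide:
    seq = list(cognate.sequence)
    seq[position - 1] = residue
    return Peptide("".join(seq), name=condition_id(position, residue))


def build_xscan_library(cognate: Peptide) -> PositionalLibrary:
    """All 19 x n single-substitution variants of an n-mer cognate."""
    entries = []
    for pos in range(1, len(cognate) + 1):
        for res in AMINO_ACIDS:
            if res == cognate[pos - 1]:
                continue
            entries.append(LibraryEntry(pos, res, _substitute(cognate, pos, res)))
    return PositionalLibrary(cognate=cognate, entries=tuple(entries), scheme="xscan")


def build_ala_gly_library(cognate: Peptide) -> PositionalLibrary:
    """Alanine scan: one variant per position, glycine where cognate is Ala.

    Standard alanine-scanning convention — alanine probes every position,
    and positions already bearing alanine receive glycine instead.
    """
    entries = []
    for pos in range(1, len(cognate) + 1):
        res = "G" if cognate[pos - 1] == "A" else "A"
        entries.append(LibraryEntry(pos, res, _substitute(cognate, pos, res)))
    return PositionalLibrary(cognate=cognate, entries=tuple(entries), scheme="ala_gly")


@dataclass(frozen=True)
class ActivityMatrix:
    """Position x residue specific activities in [0, 100].

    ``values`` is indexed by 1-based position with the 20 amino acids as
    columns; cognate-residue cells are 100 by construction (the cognate
    peptide is the 100% normalization anchor).
    """

    cognate: Peptide
    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if list(v.columns) != list(AMINO_ACIDS):
            raise ValidationError("matrix columns must be the 20 amino acids")
        if list(v.index) != list(range(1, len(self.cognate) + 1)):
            raise ValidationError("matrix rows must be positions 1..n")
        if ((v < 0) | (v > 100)).any().any():
            raise ValidationError("matrix cells must lie in [0, 100]")

    @property
    def n_positions(self) -> int:
        return len(self.cognate)

    def activity(self, position: int, residue: str) -> float:
        return float(self.values.at[position, residue])

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index = [f"P{i}" for i in out.index]
        out.to_csv(path, sep="\t", index_label="position")

    @classmethod
    def from_tsv(cls, path, cognate: Peptide) -> "ActivityMatrix":
        df = pd.read_csv(path, sep="\t", index_col="position")
        df.index = [int(str(p).lstrip("P")) for p in df.index]
        return cls(cognate=cognate, values=df[list(AMINO_ACIDS)].astype(float))


def assemble_matrix(
    library: PositionalLibrary,
    normalized: Mapping[str, SpecificValue | float | Sequence[float]],
) -> ActivityMatrix:
    """Fill the activity matrix from normalized per-condition values.

    ``normalized`` maps condition ids (``P<pos>_<res>``) to a single
    specific value or a sequence of replicate values (replicates are
    averaged after per-replicate clipping). Cognate cells are pinned to
    100. Any library entry without a value raises, naming the missing
    (position, residue) pairs.
    """
    n = len(library.cognate)
    values = pd.DataFrame(0.0, index=range(1, n + 1), columns=list(AMINO_ACIDS))
    missing = []
    for entry in library.entries:
        try:
            v = normalized[entry.condition_id]
        except KeyError:
            missing.append((entry.position, entry.residue))
            continue
        if isinstance(v, SpecificValue):
            val = v.value
        elif isinstance(v, (int, float)):
            val = float(v)
        else:
            val = aggregate_replicates(list(v)).mean
        values.at[entry.position, entry.residue] = val
    if missing:
        raise MissingDataError(
            f"no normalized value for {len(missing)} library entr(y/ies): {missing}"
        )
    for pos in range(1, n + 1):
        values.at[pos, library.cognate[pos - 1]] = 100.0
    return ActivityMatrix(cognate=library.cognate, values=values)


@dataclass(frozen=True)
class RecognitionMotif:
    """Per-position sets of residues tolerated at >= threshold activity."""

    cognate: Peptide
    sets: tuple[frozenset, ...]
    threshold: float = 50.0

    def __post_init__(self) -> None:
        if len(self.sets) != len(self.cognate):
            raise ValidationError("one residue set per cognate position required")
        for i, s in enumerate(self.sets):
            if not s:
                raise ValidationError(f"empty residue set at P{i + 1}")
            if self.cognate[i] not in s:
                raise ValidationError(
                    f"cognate residue {self.cognate[i]} missing from P{i + 1} set"
                )

    def __len__(self) -> int:
        return len(self.sets)

    def matches(self, sequence: str) -> bool:
        """True iff every residue of ``sequence`` is tolerated at its position."""
        if len(sequence) != len(self.sets):
            return False
        return all(res in s for res, s in zip(sequence, self.sets))

    def to_dict(self) -> dict:
        return {
            "cognate": self.cognate.sequence,
            "threshold": self.threshold,
            "sets": ["".join(sorted(s)) for s in self.sets],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RecognitionMotif":
        return cls(
            cognate=Peptide(d["cognate"]),
            sets=tuple(frozenset(s) for s in d["sets"]),
            threshold=float(d["threshold"]),
        )


def extract_motif(matrix: ActivityMatrix, threshold: float = 50.0) -> RecognitionMotif:
    """Allowed residues per position: activity >= threshold (inclusive).

    The cognate residue is always included (its cell is the 100% anchor).
    """
    if not 0 < threshold <= 100:
        raise ValidationError("threshold must be in (0, 100]")
    sets = []
    for pos in range(1, matrix.n_positions + 1):
        allowed = {r for r in AMINO_ACIDS if matrix.activity(pos, r) >= threshold}
        allowed.add(matrix.cognate[pos - 1])
        sets.append(frozenset(allowed))
    return RecognitionMotif(cognate=matrix.cognate, sets=tuple(sets), threshold=threshold)


@dataclass(frozen=True)
class LogoModel:
    """Per-position letter stacks with activity-proportional heights.

    Heights are specific activity / 100 for residues at or above the
    threshold — linear in reporter activation, not information content.
    Within a stack letters are sorted by descending height.
    """

    stacks: tuple[tuple[tuple[str, float], ...], ...]
    threshold: float

    def __len__(self) -> int:
        return len(self.stacks)


def build_logo(matrix: ActivityMatrix, threshold: float = 50.0) -> LogoModel:
    """Logo stacks from an activity matrix at the given threshold."""
    stacks = []
    for pos in range(1, matrix.n_positions + 1):
        entries = [
            (r, matrix.activity(pos, r) / 100.0)
            for r in AMINO_ACIDS
            if matrix.activity(pos, r) >= threshold
        ]
        entries.sort(key=lambda e: (-e[1], e[0]))
        stacks.append(tuple(entries))
    return LogoModel(stacks=tuple(stacks), threshold=threshold)


def plot_logo(logo: LogoModel, ax=None):
    """Render a logo as stacked letters (matplotlib axes)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(0.6 * len(logo), 2.5))
    for i, stack in enumerate(logo.stacks):
        y = 0.0
        for residue, height in reversed(stack):  # tallest on top
            ax.text(
                i + 1,
                y + height / 2,
                residue,
                ha="center",
                va="center",
                fontsize=8 + 10 * height,
                family="monospace",
            )
            y += height
    ax.set_xlim(0.5, len(logo) + 0.5)
    ax.set_ylim(0, max((sum(h for _, h in s) for s in logo.stacks), default=1.0) * 1.05)
    ax.set_xticks(range(1, len(logo) + 1))
    ax.set_xticklabels([f"P{i}" for i in range(1, len(logo) + 1)])
    ax.set_ylabel("specific activity / 100")
    return ax
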