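"""Degenerate-pattern proteome scanning and affinity-filtered curation.

A recognition motif compiles to a PROSITE-style pattern (plain letter
for a singleton set, ``x`` for a fully tolerant position, ``[...]``
otherwise). Scanning reports every window of a protein whose residues
all lie in the per-position sets — overlapping windows included, in
deterministic (protein id, start) order. Matches are then curated with
a pHLA-affinity filter: candidates must have a predicted binding
EC50 at or below a threshold (500 nM by default), and windows equal to
the cognate epitope are flagged rather than counted as noncognate.

Affinity predictions normally arrive as a table produced by an external
predictor (e.g. NetMHC); a small built-in anchor-residue scorer is
provided so the pipeline runs end to end without one.
"""

from __future__ import annotations

import hashlib
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import MissingPredictionError, ValidationError
from .peptide import AMINO_ACIDS, AMINO_ACID_SET, Peptide
from .xscan import RecognitionMotif

__all__ = [
    "DegeneratePattern",
    "ProteomeMatch",
    "AffinityPrediction",
    "CandidateSet",
    "compile_pattern",
    "parse_pattern",
    "scan_proteome",
    "filter_by_affinity",
    "builtin_anchor_scorer",
    "read_proteome",
    "read_predictions",
]


@dataclass(frozen=True)
class DegeneratePattern:
    """A positional residue-class pattern, e.g. ``V-[ILV]-V-x-A``."""

    per_position_sets: tuple[frozenset, ...]
    pattern_text: str

    def __post_init__(self) -> None:
        if not self.per_position_sets:
            raise ValidationError("pattern must have at least one position")
        for i, s in enumerate(self.per_position_sets):
            if not s:
                raise ValidationError(f"empty residue set at pattern position {i + 1}")
            bad = set(s) - AMINO_ACID_SET
            if bad:
                raise ValidationError(f"non-canonical residues in pattern: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.per_position_sets)


def _element_text(s: frozenset) -> str:
    if len(s) == len(AMINO_ACID_SET):
        return "x"
    if len(s) == 1:
        return next(iter(s))
    return "[" + "".join(sorted(s)) + "]"


def compile_pattern(motif: RecognitionMotif) -> DegeneratePattern:
    """Compile a recognition motif's per-position sets into a pattern."""
    sets = tuple(frozenset(s) for s in motif.sets)
    text = "-".join(_element_text(s) for s in sets)
    return DegeneratePattern(per_position_sets=sets, pattern_text=text)


_ELEMENT_RE = re.compile(r"^(?:[A-Z]|x|\[[A-Z]+\])$")


def parse_pattern(text: str) -> DegeneratePattern:
    """Parse a PROSITE-style pattern string back into per-position sets."""
    sets = []
    for elem in text.split("-"):
        if not _ELEMENT_RE.match(elem):
            raise ValidationError(f"malformed pattern element {elem!r}")
        if elem == "x":
            sets.append(frozenset(AMINO_ACID_SET))
        elif elem.startswith("["):
            sets.append(frozenset(elem[1:-1]))
        else:
            sets.append(frozenset(elem))
    return DegeneratePattern(
        per_position_sets=tuple(sets),
        pattern_text="-".join(_element_text(s) for s in sets),
    )


@dataclass(frozen=True)
class ProteomeMatch:
    protein_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    matched_sequence: str
    is_cognate: bool = False


def read_proteome(path) -> list[tuple[str, str]]:
    """Read a FASTA proteome as (id, uppercase sequence) pairs.

    Raises on a file that does not begin with a header line (reporting
    the offending line number) and on duplicate record ids.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValidationError(
                    f"malformed FASTA: line {lineno} precedes any '>' header"
                )
            break
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    ids = [rid for rid, _ in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate FASTA record id(s): {dupes}")
    return records


def scan_proteome(
    pattern: DegeneratePattern,
    proteome: Iterable[tuple[str, str]],
    cognate: str | None = None,
) -> list[ProteomeMatch]:
    """Report every window matching the pattern, overlaps included.

    Proteome records are (id, sequence) pairs; non-canonical residues
    (X, U, B, ...) never match any position class. Output order is
    deterministic: by protein id, then start coordinate. Windows equal
    to ``cognate`` are flagged ``is_cognate``.
    """
    n = len(pattern)
    # Byte-indexed lookup tables, one per pattern position.
    tables = np.zeros((n, 256), dtype=bool)
    for i, s in enumerate(pattern.per_position_sets):
        for res in s:
            tables[i, ord(res)] = True

    matches: list[ProteomeMatch] = []
    for protein_id, seq in sorted(proteome, key=lambda r: r[0]):
        L = len(seq)
        if L < n:
            continue
        codes = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
        ok = tables[0][codes[0 : L - n + 1]].copy()
        for i in range(1, n):
            ok &= tables[i][codes[i : L - n + i + 1]]
        for start0 in np.flatnonzero(ok):
            sub = seq[start0 : start0 + n]
            matches.append(
                ProteomeMatch(
                    protein_id=protein_id,
                    start=int(start0) + 1,
                    end=int(start0) + n,
                    matched_sequence=sub,
                    is_cognate=(cognate is not None and sub == cognate),
                )
            )
    return matches


@dataclass(frozen=True)
class AffinityPrediction:
    peptide: str
    allele: str
    predicted_ec50: float  # nM
    predictor_id: str = "external"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.predicted_ec50) and self.predicted_ec50 > 0):
            raise ValidationError(
                f"predicted EC50 must be finite and positive, got {self.predicted_ec50}"
            )


@dataclass(frozen=True)
class ExcludedMatch:
    match: ProteomeMatch
    prediction: AffinityPrediction
    reason: str


@dataclass(frozen=True)
class CandidateSet:
    """Curated noncognate candidates plus the exclusion ledger."""

    candidates: tuple[tuple[ProteomeMatch, AffinityPrediction], ...]
    excluded: tuple[ExcludedMatch, ...]
    cognate_matches: tuple[ProteomeMatch, ...]
    threshold_nm: float
    allele: str

    @property
    def candidate_peptides(self) -> list[str]:
        return sorted({m.matched_sequence for m, _ in self.candidates})


def read_predictions(path) -> list[AffinityPrediction]:
    """Read an external predictor table: peptide, allele, affinity_nM."""
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "allele": str})
    required = {"peptide", "allele", "affinity_nM"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"prediction table missing column(s): {sorted(missing)}")
    predictor = "external"
    if "predictor_id" in df.columns and len(df):
        predictor = str(df["predictor_id"].iloc[0])
    return [
        AffinityPrediction(
            peptide=row.peptide,
            allele=row.allele,
            predicted_ec50=float(row.affinity_nM),
            predictor_id=predictor,
        )
        for row in df.itertuples()
    ]


def filter_by_affinity(
    matches: Sequence[ProteomeMatch],
    predictions: Iterable[AffinityPrediction],
    allele: str,
    threshold_nm: float = 500.0,
) -> CandidateSet:
    """Keep noncognate matches with predicted EC50 <= threshold (inclusive).

    Matches above the threshold land in the exclusion ledger with reason
    ``"affinity"``; cognate-flagged matches are segregated and never
    counted as candidates. Every unique noncognate sequence must have a
    prediction for ``allele``, otherwise the uncovered peptides are
    reported in one error.
    """
    if threshold_nm <= 0:
        raise ValidationError("affinity threshold must be positive")
    table = {p.peptide: p for p in predictions if p.allele == allele}
    cognate_matches = tuple(m for m in matches if m.is_cognate)
    noncognate = [m for m in matches if not m.is_cognate]
    uncovered = sorted({m.matched_sequence for m in noncognate} - set(table))
    if uncovered:
        raise MissingPredictionError(
            f"no {allele} prediction for peptide(s): {uncovered}"
        )
    kept, excluded = [], []
    for m in noncognate:
        pred = table[m.matched_sequence]
        if pred.predicted_ec50 <= threshold_nm:
            kept.append((m, pred))
        else:
            excluded.append(ExcludedMatch(match=m, prediction=pred, reason="affinity"))
    return CandidateSet(
        candidates=tuple(kept),
        excluded=tuple(excluded),
        cognate_matches=cognate_matches,
        threshold_nm=threshold_nm,
        allele=allele,
    )


# ---------------------------------------------------------------------------
# Built-in anchor-residue scorer
# ---------------------------------------------------------------------------

_BUILTIN_ALLELES = {"A*03:01", "A*11:01", "HLA-A*03:01", "HLA-A*11:01"}

# Position-weight contributions for the two canonical class I anchors of the
# HLA-A3 superfamily: small/aliphatic residues at P2 and a basic C-terminus
# (K/R), the motif its epitopes — including the KRAS G12V ...GVGK peptides —
# carry experimentally.
_P2_WEIGHTS = {"L": 3.0, "I": 3.0, "V": 2.5, "M": 2.5, "T": 2.0, "S": 2.0}
_CTERM_WEIGHTS = {"K": 4.0, "R": 3.5}
_SCALE_NM = 5.0e4  # pseudo-EC50 at zero anchor score


def builtin_anchor_scorer(peptide: Peptide | str, allele: str) -> AffinityPrediction:
    """Deterministic pseudo-EC50 from a shipped anchor position-weight matrix.

    A coarse stand-in predictor (id ``builtin-anchor-pwm``) for running
    the pipeline without an external affinity table: the score rewards
    the A3-superfamily P2 and C-terminal anchors and maps monotonically
    to a pseudo-EC50 in nM (higher score, lower EC50). Not a trained
    binding model — candidate lists derived from it are illustrative.
    """
    pep = peptide if isinstance(peptide, Peptide) else Peptide(peptide)
    if not 8 <= len(pep) <= 11:
        raise ValidationError(
            f"builtin scorer handles 8-11-mers, got length {len(pep)}"
        )
    if allele not in _BUILTIN_ALLELES:
        raise ValidationError(
            f"builtin scorer ships matrices for A*03:01 / A*11:01 only, got {allele!r}"
        )
    score = _P2_WEIGHTS.get(pep[1], 0.0) + _CTERM_WEIGHTS.get(pep[-1], 0.0)
    ec50_nm = _SCALE_NM * math.exp(-score)
    return AffinityPrediction(
        peptide=pep.sequence,
        allele=allele,
        predicted_ec50=ec50_nm,
        predictor_id="builtin-anchor-pwm",
    )


def proteome_checksum(path) -> str:
    """SHA-256 of a proteome file, recorded so candidate lists are traceable."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
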