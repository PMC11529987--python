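"""Absolute pHLA quantitation from targeted-MS (PRM) peak areas.

Each injection carries the analyte ("light") peptide eluted from the
HLA immunoprecipitate alongside a stable-isotope-labeled ("heavy")
internal standard spiked at a known amount (200 fmol in the reference
design). The light/heavy peak-area ratio times the spike amount gives
the moles of analyte in the injection; dividing by the injected
fraction of the enriched sample (0.5 when half the IP goes into each
of duplicate injections) yields total moles eluted, which Avogadro's
number converts to molecules and the input cell count normalizes to
copies per cell.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .peptide import Peptide

__all__ = [
    "AVOGADRO",
    "Injection",
    "PRMSample",
    "AbundanceClass",
    "CopiesPerCellResult",
    "copies_per_cell",
    "classify_abundance",
    "Trace",
    "IdentityResult",
    "confirm_identity",
    "read_prm_table",
]

AVOGADRO = 6.02214076e23  # mol^-1


@dataclass(frozen=True)
class Injection:
    light_area: float  # arbitrary units, >= 0
    heavy_area: float  # arbitrary units, > 0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.light_area) and self.light_area >= 0):
            raise ValidationError(f"light_area must be finite and >= 0, got {self.light_area}")
        if not (math.isfinite(self.heavy_area) and self.heavy_area > 0):
            raise ValidationError(f"heavy_area must be finite and > 0, got {self.heavy_area}")

    @property
    def ratio(self) -> float:
        return self.light_area / self.heavy_area


@dataclass(frozen=True)
class PRMSample:
    sample_id: str
    injections: tuple[Injection, ...]
    spike_amount: float  # mol (200 fmol = 2e-13 mol in the reference design)
    injected_fraction: float  # fraction of the enriched sample per injection
    input_cells: float
    peptide: Peptide | None = None
    allele: str = ""

    def __post_init__(self) -> None:
        if not self.injections:
            raise ValidationError("PRM sample needs at least one injection")
        if not (math.isfinite(self.spike_amount) and self.spike_amount > 0):
            raise ValidationError("spike_amount must be positive (mol)")
        if not 0 < self.injected_fraction <= 1:
            raise ValidationError("injected_fraction must be in (0, 1]")
        # A slight tolerance: equal splits like 2 x 0.5 are exactly 1.
        if self.injected_fraction * len(self.injections) > 1.0 + 1e-9:
            raise ValidationError(
                "injections consume more than the whole enriched sample"
            )
        if not (math.isfinite(self.input_cells) and self.input_cells > 0):
            raise ValidationError("input_cells must be positive")


class AbundanceClass(str, enum.Enum):
    HIGH = "high"
    INTERMEDIATE = "intermediate"
    LOW = "low"


@dataclass(frozen=True)
class CopiesPerCellResult:
    copies_per_cell: float
    moles_eluted_total: float
    abundance_class: AbundanceClass
    per_injection_values: tuple[float, ...]  # copies/cell implied by each injection
    bounds: tuple[float, float]


def classify_abundance(
    copies: float, bounds: tuple[float, float] = (35.0, 75.0)
) -> AbundanceClass:
    """Bin a copies/cell value as low / intermediate / high.

    Published per-cell-line ranges overlap, so the bin edges are explicit
    configuration (defaults 35 and 75 copies/cell) rather than a claim
    about any particular cell line.
    """
    if copies < 0:
        raise ValidationError("copies must be >= 0")
    low_hi, int_hi = bounds
    if not 0 < low_hi < int_hi:
        raise ValidationError("bounds must satisfy 0 < low_hi < int_hi")
    if copies <= low_hi:
        return AbundanceClass.LOW
    if copies <= int_hi:
        return AbundanceClass.INTERMEDIATE
    return AbundanceClass.HIGH


def copies_per_cell(
    sample: PRMSample, bounds: tuple[float, float] = (35.0, 75.0)
) -> CopiesPerCellResult:
    """Copies of the peptide per input cell from light/heavy peak areas.

    Per injection, moles = (light/heavy) x spike. Duplicate injections
    are averaged on the ratio scale, then scaled to the whole sample by
    dividing by the injected fraction (doubling when half the IP is
    injected), converted to molecules with Avogadro's number, and
    divided by the number of input cells.
    """
    per_inj_moles = [inj.ratio * sample.spike_amount for inj in sample.injections]
    mean_inj = float(np.mean(per_inj_moles))
    total = mean_inj / sample.injected_fraction
    copies = total * AVOGADRO / sample.input_cells
    per_inj_copies = tuple(
        m / sample.injected_fraction * AVOGADRO / sample.input_cells
        for m in per_inj_moles
    )
    return CopiesPerCellResult(
        copies_per_cell=copies,
        moles_eluted_total=total,
        abundance_class=classify_abundance(copies, bounds),
        per_injection_values=per_inj_copies,
        bounds=bounds,
    )


# ---------------------------------------------------------------------------
# Identity confirmation from retention-time traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Trace:
    """A chromatographic trace: retention times (min) and intensities.

    ``fragment_intensities`` optionally carries per-fragment peak
    intensities (e.g. y-ion series) for rank-order comparison.
    """

    times: np.ndarray
    intensities: np.ndarray
    fragment_intensities: dict[str, float] | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", x)
        if t.size == 0 or t.shape != x.shape:
            raise ValidationError("trace needs equal-length, nonempty times/intensities")

    @property
    def apex_rt(self) -> float:
        return float(self.times[int(np.argmax(self.intensities))])

    def fragment_rank_order(self) -> tuple[str, ...] | None:
        if self.fragment_intensities is None:
            return None
        return tuple(
            sorted(self.fragment_intensities, key=lambda k: (-self.fragment_intensities[k], k))
        )


@dataclass(frozen=True)
class IdentityResult:
    confirmed: bool
    rt_delta: float  # |apex RT light - apex RT heavy|, minutes
    rank_order_match: bool | None  # None when either trace lacks fragment data


def confirm_identity(
    light: Trace, heavy: Trace, rt_tolerance: float = 0.2
) -> IdentityResult:
    """Confirm analyte identity against the heavy standard.

    Confirmed when the apex retention times agree within the tolerance
    (default 0.2 min) and, where both traces carry fragment intensities,
    the fragment rank orders match.
    """
    rt_delta = abs(light.apex_rt - heavy.apex_rt)
    lo, ho = light.fragment_rank_order(), heavy.fragment_rank_order()
    rank_match: bool | None
    if lo is None or ho is None:
        rank_match = None
    else:
        rank_match = lo == ho
    confirmed = rt_delta <= rt_tolerance and rank_match is not False
    return IdentityResult(confirmed=confirmed, rt_delta=rt_delta, rank_order_match=rank_match)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

PRM_COLUMNS = (
    "sample_id",
    "peptide",
    "allele",
    "injection_id",
    "light_area",
    "heavy_area",
    "spike_fmol",
    "injected_fraction",
    "input_cells",
)


def read_prm_table(path) -> list[PRMSample]:
    """Read a PRM peak-area table (TSV, one row per injection)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "peptide": str, "allele": str})
    missing = set(PRM_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"PRM table missing column(s): {sorted(missing)}")
    samples = []
    for sid, grp in df.groupby("sample_id", sort=True):
        first = grp.iloc[0]
        samples.append(
            PRMSample(
                sample_id=str(sid),
                injections=tuple(
                    Injection(light_area=float(r.light_area), heavy_area=float(r.heavy_area))
                    for r in grp.itertuples()
                ),
                spike_amount=float(first["spike_fmol"]) * 1e-15,
                injected_fraction=float(first["injected_fraction"]),
                input_cells=float(first["input_cells"]),
                peptide=Peptide(str(first["peptide"])),
                allele=str(first["allele"]),
            )
        )
    return samples
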