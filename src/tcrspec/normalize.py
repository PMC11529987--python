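"""Normalization of reporter and cytotoxicity readouts to specific values.

A raw readout (%GFP-positive reporter cells, or released counts in a
51Cr assay) is mapped linearly between two anchor conditions:

    specific value (%) = (test - min) / (max - min) * 100

with the no-stimulus condition pinned to 0% and a maximal-activation
anchor pinned to 100%. Values outside [0, 100] are trimmed to the
nearest bound and flagged. The maximal anchor differs by assay design:
cognate-peptide-pulsed targets for dose-response work, PMA-ionomycin
for positional-scan heatmaps, or detergent lysis for release assays —
the mode used is recorded alongside every normalized value.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateAnchorError, ValidationError


class AnchorMode(str, enum.Enum):
    """Which condition supplied the 100% anchor."""

    COGNATE = "cognate"
    PMA_I = "pma_i"
    DETERGENT = "detergent"


@dataclass(frozen=True)
class ReporterReadout:
    """One raw measurement of one condition in one replicate."""

    condition_id: str
    raw_value: float
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        if not self.condition_id:
            raise ValidationError("condition_id must be nonempty")
        if not math.isfinite(self.raw_value):
            raise ValidationError(f"raw_value must be finite, got {self.raw_value}")
        if self.raw_value < 0:
            raise ValidationError(f"raw_value must be >= 0, got {self.raw_value}")


@dataclass(frozen=True)
class NormalizationAnchors:
    """The 0% and 100% reference readouts, in raw-readout units."""

    min_value: float
    max_value: float
    anchor_mode: AnchorMode = AnchorMode.COGNATE

    def __post_init__(self) -> None:
        for v in (self.min_value, self.max_value):
            if not math.isfinite(v):
                raise ValidationError(f"anchor value must be finite, got {v}")
        if self.max_value <= self.min_value:
            raise DegenerateAnchorError(
                f"max anchor ({self.max_value}) must exceed min anchor "
                f"({self.min_value})"
            )


@dataclass(frozen=True)
class SpecificValue:
    """A normalized percentage in [0, 100] with trimming provenance."""

    value: float
    clipped_low: bool = False
    clipped_high: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 100.0:
            raise ValidationError(f"specific value {self.value} outside [0, 100]")


@dataclass(frozen=True)
class ReplicateSummary:
    mean: float
    sd: float
    n: int


def specific_activity(test: float, anchors: NormalizationAnchors) -> SpecificValue:
    """Normalize a reporter readout between the anchor conditions.

    Values above 100% are trimmed to 100 and negative values adjusted to
    zero, with the corresponding flag set.
    """
    if not math.isfinite(test):
        raise ValidationError(f"test readout must be finite, got {test}")
    raw = (test - anchors.min_value) / (anchors.max_value - anchors.min_value) * 100.0
    clipped_low = raw < 0.0
    clipped_high = raw > 100.0
    return SpecificValue(
        value=min(max(raw, 0.0), 100.0),
        clipped_low=clipped_low,
        clipped_high=clipped_high,
    )


def specific_lysis(test: float, spontaneous: float, maximal: float) -> SpecificValue:
    """Specific lysis (%) from release counts: (test - min)/(max - min) x 100.

    Spontaneous release anchors 0% and maximal (detergent) release 100%;
    the same trimming rules as :func:`specific_activity` apply.
    """
    anchors = NormalizationAnchors(
        min_value=spontaneous, max_value=maximal, anchor_mode=AnchorMode.DETERGENT
    )
    return specific_activity(test, anchors)


def aggregate_replicates(
    values: Sequence[SpecificValue | float],
) -> ReplicateSummary:
    """Mean and sample (n-1) standard deviation over replicate values.

    Clipping happens per replicate upstream, so the mean stays in [0, 100].
    With a single replicate the sd is reported as 0.
    """
    vals = [v.value if isinstance(v, SpecificValue) else float(v) for v in values]
    if not vals:
        raise ValidationError("cannot aggregate zero replicates")
    arr = np.asarray(vals, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return ReplicateSummary(mean=float(arr.mean()), sd=sd, n=arr.size)


# ---------------------------------------------------------------------------
# Tabular I/O: long-format readout tables
# ---------------------------------------------------------------------------

READOUT_COLUMNS = ("condition_id", "replicate_id", "raw_value", "role")
_ROLES = {"test", "min", "max"}


def read_readouts(path) -> pd.DataFrame:
    """Read a long-format readout table (TSV) with a role column."""
    df = pd.read_csv(path, sep="\t", dtype={"condition_id": str, "replicate_id": str})
    missing = set(READOUT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"readout table missing column(s): {sorted(missing)}")
    bad_roles = set(df["role"]) - _ROLES
    if bad_roles:
        raise ValidationError(f"unknown role(s) in readout table: {sorted(bad_roles)}")
    return df


def anchors_from_table(
    df: pd.DataFrame, anchor_mode: AnchorMode = AnchorMode.COGNATE
) -> NormalizationAnchors:
    """Derive anchors from the min/max-role rows (replicate means)."""
    mins = df.loc[df["role"] == "min", "raw_value"]
    maxs = df.loc[df["role"] == "max", "raw_value"]
    if mins.empty or maxs.empty:
        raise ValidationError("readout table needs at least one min and one max row")
    return NormalizationAnchors(
        min_value=float(mins.mean()),
        max_value=float(maxs.mean()),
        anchor_mode=anchor_mode,
    )


def normalize_table(
    df: pd.DataFrame,
    anchors: NormalizationAnchors | None = None,
    anchor_mode: AnchorMode = AnchorMode.COGNATE,
) -> pd.DataFrame:
    """Normalize every test-role row; returns a tidy per-replicate table.

    Columns: condition_id, replicate_id, value, clipped_low, clipped_high,
    anchor_mode. Clipping is applied per replicate, before any averaging.
    """
    if anchors is None:
        anchors = anchors_from_table(df, anchor_mode)
    rows = []
    for _, row in df.loc[df["role"] == "test"].iterrows():
        sv = specific_activity(float(row["raw_value"]), anchors)
        rows.append(
            {
                "condition_id": row["condition_id"],
                "replicate_id": row["replicate_id"],
                "value": sv.value,
                "clipped_low": sv.clipped_low,
                "clipped_high": sv.clipped_high,
                "anchor_mode": anchors.anchor_mode.value,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "condition_id",
            "replicate_id",
            "value",
            "clipped_low",
            "clipped_high",
            "anchor_mode",
        ],
    )


def summarize_conditions(normalized: pd.DataFrame) -> pd.DataFrame:
    """Replicate mean +/- sd per condition from a normalize_table result."""
    out = []
    for cond, grp in normalized.groupby("condition_id", sort=True):
        summ = aggregate_replicates(list(grp["value"]))
        out.append(
            {"condition_id": cond, "mean": summ.mean, "sd": summ.sd, "n": summ.n}
        )
    return pd.DataFrame(out, columns=["condition_id", "mean", "sd", "n"])


def condition_values(normalized: pd.DataFrame) -> dict[str, float]:
    """condition_id -> replicate-mean specific value."""
    summary = summarize_conditions(normalized)
    return dict(zip(summary["condition_id"], summary["mean"]))
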