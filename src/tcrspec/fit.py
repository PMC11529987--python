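"""Nonlinear regression: 4PL dose-response (EC50), avidity deltas, KT50.

Dose-response curves follow the four-parameter logistic in log10
concentration,

    response(c) = bottom + (top - bottom) / (1 + (EC50 / c)^hill),

the model behind "[agonist] vs. normalized response" fits in standard
curve-fitting software. EC50 is the concentration at half-maximal
response; functional avidity differences between two ligands or
receptor configurations are expressed as delta log10(EC50).

Kill curves (viability index normalized to 1 at effector addition) are
fit to a single-exponential decay index(t) = exp(-k t); the time to 50%
target killing is KT50 = ln 2 / k, censored when the fitted curve never
crosses 0.5 within the observation window.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import FlatCurveError, ValidationError

__all__ = [
    "DoseResponseSeries",
    "DoseResponseFit",
    "AvidityComparison",
    "CD8DependenceClass",
    "CD8Dependence",
    "KillCurve",
    "KT50Result",
    "fit_4pl",
    "compare_avidity",
    "cd8_dependence",
    "fit_kt50",
    "kt50_closed_form",
]


@dataclass(frozen=True)
class DoseResponseSeries:
    """Paired (concentration, response) measurements for one ligand.

    Concentrations are molar and strictly positive; responses are
    specific activities in [0, 100]. A meaningful 4PL fit needs at
    least 5 distinct concentrations spanning >= 2 decades.
    """

    concentrations: np.ndarray
    responses: np.ndarray
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        resp = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "responses", resp)
        if conc.shape != resp.shape or conc.ndim != 1:
            raise ValidationError("concentrations and responses must be equal-length 1-D")
        if not np.all(np.isfinite(conc)) or not np.all(np.isfinite(resp)):
            raise ValidationError("non-finite values in dose-response series")
        if np.any(conc <= 0):
            raise ValidationError("concentrations must be strictly positive (molar)")
        if np.any((resp < 0) | (resp > 100)):
            raise ValidationError("responses must be specific activities in [0, 100]")

    @property
    def log10_span(self) -> float:
        return float(np.log10(self.concentrations.max() / self.concentrations.min()))


@dataclass(frozen=True)
class DoseResponseFit:
    ec50: float  # molar
    hill: float
    top: float
    bottom: float
    converged: bool
    rss: float
    extrapolated: bool = False  # EC50 outside the tested concentration range

    @property
    def log10_ec50(self) -> float:
        return math.log10(self.ec50)


@dataclass(frozen=True)
class AvidityComparison:
    """delta_log10_ec50 = log10(ec50_b / ec50_a); positive means b is weaker."""

    ec50_a: float
    ec50_b: float
    delta_log10_ec50: float


class CD8DependenceClass(str, enum.Enum):
    INDEPENDENT = "independent"
    PARTIAL = "partial"
    DEPENDENT = "dependent"


@dataclass(frozen=True)
class CD8Dependence:
    comparison: AvidityComparison
    dependence_class: CD8DependenceClass
    boundaries: tuple[float, float]


def _fourpl(logc: np.ndarray, log_ec50: float, hill: float, top: float, bottom: float):
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - logc) * hill))


def fit_4pl(
    series: DoseResponseSeries,
    top_bounds: tuple[float, float] = (0.0, 120.0),
    bottom_bounds: tuple[float, float] = (-20.0, 100.0),
) -> DoseResponseFit:
    """Least-squares 4PL fit in log10-concentration space.

    Initialization is deterministic: hill = 1, top/bottom from the data
    extremes, EC50 at the concentration whose response is nearest
    half-maximal. EC50 is bounded within two decades of the tested range;
    a fitted value outside the tested range is flagged ``extrapolated``.
    Failure to converge is reported honestly via ``converged=False``
    (returning the initialization), never silently.
    """
    conc = series.concentrations
    resp = series.responses
    if len(np.unique(conc)) < 5:
        raise ValidationError("4PL fit needs >= 5 distinct concentrations")
    if series.log10_span < 2.0:
        raise ValidationError("4PL fit needs >= 2 log10 units of concentration span")
    if np.ptp(resp) == 0.0:
        raise FlatCurveError(
            "all responses identical; dose-response curve is flat and EC50 undefined"
        )

    logc = np.log10(conc)
    bottom0 = float(resp.min())
    top0 = float(resp.max())
    half = (top0 + bottom0) / 2.0
    log_ec50_0 = float(logc[np.argmin(np.abs(resp - half))])

    lo = [logc.min() - 2.0, 0.1, top_bounds[0], bottom_bounds[0]]
    hi = [logc.max() + 2.0, 10.0, top_bounds[1], bottom_bounds[1]]
    p0 = [
        min(max(log_ec50_0, lo[0]), hi[0]),
        1.0,
        min(max(top0, top_bounds[0]), top_bounds[1]),
        min(max(bottom0, bottom_bounds[0]), bottom_bounds[1]),
    ]

    try:
        popt, _ = curve_fit(_fourpl, logc, resp, p0=p0, bounds=(lo, hi), maxfev=20000)
        converged = True
    except (RuntimeError, ValueError):
        popt = p0
        converged = False

    log_ec50, hill, top, bottom = (float(v) for v in popt)
    resid = resp - _fourpl(logc, *popt)
    ec50 = 10.0**log_ec50
    return DoseResponseFit(
        ec50=ec50,
        hill=hill,
        top=top,
        bottom=bottom,
        converged=converged,
        rss=float(resid @ resid),
        extrapolated=not (conc.min() <= ec50 <= conc.max()),
    )


def compare_avidity(fit_a: DoseResponseFit, fit_b: DoseResponseFit) -> AvidityComparison:
    """Avidity difference as delta log10(EC50) = log10(ec50_b) - log10(ec50_a)."""
    for name, fit in (("a", fit_a), ("b", fit_b)):
        if not fit.converged:
            raise ValidationError(f"fit {name} did not converge; avidity undefined")
    return AvidityComparison(
        ec50_a=fit_a.ec50,
        ec50_b=fit_b.ec50,
        delta_log10_ec50=math.log10(fit_b.ec50) - math.log10(fit_a.ec50),
    )


def cd8_dependence(
    fit_cd8pos: DoseResponseFit,
    fit_cd8neg: DoseResponseFit,
    boundaries: tuple[float, float] = (0.5, 1.0),
) -> CD8Dependence:
    """Classify coreceptor dependence from the CD8+/CD8- avidity shift.

    The shift is delta log10(EC50) of the CD8-negative relative to the
    CD8-positive reporter. Below the first boundary the TCR is called
    coreceptor independent, between the boundaries partial, above the
    second dependent. The boundaries (default 0.5 and 1.0 log10) are a
    package convention, recorded in the result.
    """
    cmp_ = compare_avidity(fit_cd8pos, fit_cd8neg)
    lo, hi = boundaries
    if cmp_.delta_log10_ec50 < lo:
        cls = CD8DependenceClass.INDEPENDENT
    elif cmp_.delta_log10_ec50 <= hi:
        cls = CD8DependenceClass.PARTIAL
    else:
        cls = CD8DependenceClass.DEPENDENT
    return CD8Dependence(comparison=cmp_, dependence_class=cls, boundaries=boundaries)


# ---------------------------------------------------------------------------
# Kill curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KillCurve:
    """Normalized viability index over time (index(0) = 1)."""

    times: np.ndarray  # hours, increasing, starting at 0
    index: np.ndarray  # normalized viability, >= 0
    effector_target_ratio: float | None = None
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.index, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "index", x)
        if t.shape != x.shape or t.ndim != 1:
            raise ValidationError("times and index must be equal-length 1-D")
        if t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing from 0")
        if not np.all(np.isfinite(x)) or np.any(x < 0):
            raise ValidationError("index values must be finite and >= 0")

    @property
    def t_max(self) -> float:
        return float(self.times[-1])


@dataclass(frozen=True)
class KT50Result:
    """Time to 50% target killing, or censored at the observation window."""

    kt50: float | None  # hours; None when censored
    censored: bool
    t_max: float
    rate: float  # fitted decay rate k (1/h)
    method: str = "regression"
    outgrowth: bool = False  # index increased: targets outgrew killing

    @property
    def label(self) -> str:
        return f"{self.kt50:.3g} h" if self.kt50 is not None else f">{self.t_max:g} h"


def kt50_closed_form(k: float) -> float:
    """KT50 of a pure exponential decay with rate k: ln 2 / k."""
    if k <= 0:
        raise ValidationError("decay rate must be positive")
    return math.log(2.0) / k


def fit_kt50(curve: KillCurve) -> KT50Result:
    """Fit index(t) = exp(-k t) and report the 0.5 crossing time.

    Censored (kt50 = None) when the fitted curve does not reach 0.5
    within the observation window; an increasing index (target
    outgrowth) is censored with the ``outgrowth`` flag set.
    """
    if curve.times.size < 6:
        raise ValidationError("KT50 fit needs >= 6 time points")
    t, x = curve.times, curve.index

    # Deterministic initialization from a log-linear regression.
    slope = float(np.polyfit(t, np.log(np.clip(x, 1e-6, None)), 1)[0])
    k0 = max(-slope, 1e-6)

    def model(tt, k):
        return np.exp(-k * tt)

    try:
        popt, _ = curve_fit(model, t, x, p0=[k0], bounds=(0.0, np.inf), maxfev=10000)
        k = float(popt[0])
    except (RuntimeError, ValueError):
        k = k0

    outgrowth = slope > 0 and k <= 1e-9
    if k <= 1e-9:
        return KT50Result(
            kt50=None, censored=True, t_max=curve.t_max, rate=k, outgrowth=outgrowth
        )
    kt50 = kt50_closed_form(k)
    if kt50 > curve.t_max:
        return KT50Result(kt50=None, censored=True, t_max=curve.t_max, rate=k)
    return KT50Result(kt50=kt50, censored=False, t_max=curve.t_max, rate=k)
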