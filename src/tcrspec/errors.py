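"""Exception hierarchy.

Everything raised on bad input derives from :class:`ValidationError`
(a ``ValueError``), so callers can catch one type for malformed data.
"""


class TcrspecError(Exception):
    """Base class for package errors."""


class ValidationError(TcrspecError, ValueError):
    """Invalid input data (non-finite values, bad sequences, ...)."""


class DegenerateAnchorError(ValidationError):
    """Normalization anchors with max <= min."""


class FlatCurveError(TcrspecError):
    """Dose-response series with no dynamic range; a 4PL fit is undefined."""


class MissingDataError(TcrspecError):
    """A required measurement (library entry, condition) is absent."""


class MissingPredictionError(TcrspecError):
    """An affinity prediction is missing for a matched peptide."""


class ConfigError(TcrspecError):
    """Invalid pipeline configuration; carries the full list of problems."""

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))
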