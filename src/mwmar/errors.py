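"""Exception hierarchy.

All user-facing failures derive from :class:`MWMARError` so callers can
catch one type at the CLI boundary.  Input problems (bad shapes, misaligned
time indices, invalid settings) raise :class:`InputError`; a regression
design that cannot be solved (constant predictor column, too few rows)
raises :class:`DegenerateFitError` naming the offending equation; a run in
which nothing succeeded raises :class:`RunError`.
"""


class MWMARError(Exception):
    """Base class for all package errors."""


class InputError(MWMARError, ValueError):
    """Invalid, inconsistent or misaligned inputs."""


class DegenerateFitError(MWMARError, RuntimeError):
    """A per-equation least-squares design is rank deficient or too small."""

    def __init__(self, equation: str, reason: str):
        self.equation = equation
        self.reason = reason
        super().__init__(f"degenerate fit for equation {equation!r}: {reason}")


class RunError(MWMARError, RuntimeError):
    """An entire multi-fit run failed (e.g. every window degenerate)."""
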