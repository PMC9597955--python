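"""Exception hierarchy for case validation, the decision engine, and fixtures."""


class JadadSelectError(Exception):
    """Base class for all package-specific errors."""


class CaseError(JadadSelectError):
    """A discordant-review case violates a structural requirement
    (e.g. fewer than two systematic reviews)."""


class FixtureIntegrityError(JadadSelectError):
    """The bundled replication tables are incomplete or inconsistent."""


class StepError(JadadSelectError):
    """An algorithm step could not be evaluated.

    Carries the step identifier (``A``..``I``) so callers can report the
    failing step.
    """

    def __init__(self, step: str, message: str):
        self.step = step
        super().__init__(f"Step {step}: {message}")


class IncomparableQualityError(StepError):
    """Quality ratings from different instruments cannot be ranked against
    each other; a shared tool (or fresh ROBIS verdicts) is required."""

    def __init__(self, message: str, step: str = "D"):
        super().__init__(step, message)


class EffectClassificationError(JadadSelectError):
    """A pooled effect cannot be classified (missing or inconsistent
    significance information)."""


class ConfigError(JadadSelectError):
    """A simulation configuration is infeasible."""
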