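"""Exception hierarchy for the MR pipeline.

Every error raised on a user-facing contract violation derives from
:class:`MrError`, so callers (and the CLI) can catch one type.
"""


class MrError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MrError):
    """A summary-statistics file violates the expected layout."""


class DuplicateVariantError(FormatError):
    """A panel contains the same variant identifier more than once."""

    def __init__(self, variant_ids):
        self.variant_ids = sorted(variant_ids)
        super().__init__(f"duplicate variant_id(s): {', '.join(self.variant_ids)}")


class EmptyReportError(MrError):
    """An attempt to write a report with no rows."""


class MissingDataError(MrError):
    """A required field (e.g. effect-allele frequency) is absent."""


class NoInstrumentsError(MrError):
    """Instrument selection produced an empty set."""


class InsufficientInstrumentsError(MrError):
    """An estimator was called with fewer variants than it supports."""


class UndefinedRatioError(MrError):
    """Wald ratio requested for a variant with zero exposure effect."""


class CollinearityError(MrError):
    """Design degenerate: all exposure effects identical after orientation."""


class ConvergenceError(MrError):
    """A numerical optimisation failed to locate an interior optimum."""


class HarmonisationError(MrError):
    """Harmonisation could not proceed (e.g. zero kept records)."""


class ConfigError(MrError):
    """A run or simulation configuration is invalid."""
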