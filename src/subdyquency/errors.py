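"""Exception types shared across the package."""


class SubdyquencyError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SubdyquencyError, ValueError):
    """An input file violates its expected format."""


class CohortError(SubdyquencyError, ValueError):
    """A cohort-level contract is violated (empty cohort, mismatch, ...)."""
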