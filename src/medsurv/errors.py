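"""Typed exceptions shared across the package.

The simulation layer relies on these being distinguishable: degenerate
replicates (undefined medians, zero variance estimates) are redrawn, while
invalid inputs and bad configuration abort immediately.
"""


class MedsurvError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MedsurvError, ValueError):
    """Malformed data: wrong shapes, non-binary event flags, empty samples."""


class DegenerateDataError(MedsurvError, ValueError):
    """Data too degenerate for the test: undefined medians or zero variance."""


class ConfigurationError(MedsurvError, ValueError):
    """Unknown scenario keys, family tags, or out-of-range settings."""
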