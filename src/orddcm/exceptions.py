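"""Exception hierarchy shared across the package."""


class OrddcmError(Exception):
    """Base class for all package-specific errors."""


class DesignError(OrddcmError, ValueError):
    """Invalid measurement design (Q-matrix, W-matrix, profile space, counts)."""


class ConstraintError(OrddcmError, ValueError):
    """Model parameters violate an ordering or sign constraint."""


class DataError(OrddcmError, ValueError):
    """Response data fails validation (bad codes, shape mismatch, parse failure)."""


class ConfigError(OrddcmError, ValueError):
    """Inconsistent or incomplete run/study configuration."""
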