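"""Exception types shared across the pipeline."""


class ConfigError(ValueError):
    """A simulation or analysis configuration violates its invariants."""


class InputError(ValueError):
    """Input arrays/tables are malformed (shape mismatch, bad range)."""


class UndefinedIndexError(ZeroDivisionError):
    """Phagocytic index requested for wells with zero total cell count."""


class UndefinedSeparationError(ValueError):
    """Control groups are not separated (equal means / zero variance)."""


class RenderOverlapError(ValueError):
    """Rendered cells overlap beyond the configured cap."""
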