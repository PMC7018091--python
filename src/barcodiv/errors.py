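"""Exception hierarchy shared across the pipeline."""


class BarcodivError(Exception):
    """Base class for all pipeline errors."""


class FormatError(BarcodivError, ValueError):
    """A file does not conform to its declared format."""


class ValidationError(BarcodivError, ValueError):
    """Input data violates a structural invariant (duplicate IDs, bad tokens, ...)."""


class MissingFeatureError(BarcodivError, KeyError):
    """A named annotation feature required for region extraction is absent."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return str(self.args[0]) if self.args else ""


class EmptyRegionError(BarcodivError, ValueError):
    """A region specification resolves to zero sites (e.g. overlapping spacer anchors)."""


class UndefinedInputError(BarcodivError, ValueError):
    """A statistic is undefined for this input (e.g. no gap-free columns for pi)."""


class UndefinedPairError(BarcodivError, ValueError):
    """A sequence pair shares zero comparable columns; p-distance is undefined."""


class ParameterError(BarcodivError, ValueError):
    """An operation was called with out-of-range parameters."""
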