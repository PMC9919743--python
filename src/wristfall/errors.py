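"""Exception hierarchy shared across the package."""


class WristfallError(Exception):
    """Base class for package-specific failures."""


class FormatError(WristfallError, ValueError):
    """A file or payload does not have the expected structure."""


class DataError(WristfallError, ValueError):
    """Structurally valid input whose content violates a data invariant."""


class IntegrityError(WristfallError, ValueError):
    """A serialized artifact is inconsistent with its manifest."""


class AlignmentError(WristfallError, ValueError):
    """Two sequences that must be time-aligned are not."""
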