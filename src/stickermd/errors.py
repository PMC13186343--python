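"""Exception types raised by the package."""


class StickerMDError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(StickerMDError, ValueError):
    """An argument violates a documented precondition."""


class PackingError(StickerMDError):
    """The requested density cannot be realized by the chain packer."""


class ParseError(StickerMDError):
    """A data file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class IntegrityError(StickerMDError):
    """A restart file is truncated or missing a required section."""


class OverlapError(StickerMDError):
    """Two beads are numerically on top of each other."""


class InstabilityError(StickerMDError):
    """Per-step displacement exceeded the stability guard (dt too large?)."""


class UndefinedEquilibriumError(StickerMDError):
    """A bond-state series never visits one of the two states."""
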