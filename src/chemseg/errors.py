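"""Exception hierarchy shared across the package."""


class ChemsegError(Exception):
    """Base class for all package errors."""


class InvalidImageError(ChemsegError):
    """Page has an unsupported channel layout or intensity range."""


class InvalidParameterError(ChemsegError):
    """A numeric parameter violates its contract (e.g. even dilation kernel)."""


class EmptyMaskError(ChemsegError):
    """An operation that requires at least one True pixel received none."""


class InvalidInputError(ChemsegError):
    """Mismatched shapes or otherwise inconsistent inputs."""


class MaskPageMismatchError(InvalidInputError):
    """A mask file declares dimensions that differ from the page it targets."""


class MaskFormatError(ChemsegError):
    """Malformed mask-exchange JSON (bad RLE, missing fields)."""


class PlacementError(ChemsegError):
    """Synthetic page spec cannot place all objects without overlap."""


class InputError(ChemsegError):
    """Unreadable input document (missing, truncated or unsupported PDF)."""
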