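"""Exception hierarchy for the stalk cross-section pipeline."""


class StalksectError(Exception):
    """Base class for all package errors."""


class InputError(StalksectError):
    """Invalid user-supplied argument or precondition violation."""


class FormatError(StalksectError):
    """Unreadable or schema-incompatible file."""


class SegmentationError(StalksectError):
    """No usable stalk section could be extracted from the image."""


class GeometryError(StalksectError):
    """Degenerate geometry (zero-area or collinear contour)."""


class ResolutionError(StalksectError):
    """Requested decomposition finer than the pixel grid supports."""


class PackingError(StalksectError):
    """Phantom bundle placement infeasible under the stated constraints."""


class CollinearityError(StalksectError):
    """Perfectly collinear predictors in a regression design."""

    def __init__(self, aliased: list[str]):
        self.aliased = list(aliased)
        super().__init__(f"perfectly collinear predictors: {self.aliased}")
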