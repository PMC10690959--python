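"""Exception hierarchy."""


class MvtsegError(Exception):
    """Base class for package errors."""


class FormatError(MvtsegError, ValueError):
    """File content violates the expected format (non-3D, non-finite, ...)."""


class LabelError(MvtsegError, ValueError):
    """A label map contains a value outside the declared class set."""


class ConfigError(MvtsegError, ValueError):
    """Invalid model or run configuration."""


class ParameterError(MvtsegError, ValueError):
    """Phantom parameters are inconsistent (e.g. object cannot fit)."""


class EmptyMaskError(MvtsegError, ValueError):
    """An operation requiring foreground received an empty mask."""


class BoxError(MvtsegError, ValueError):
    """Bounding box is unusable (e.g. center outside the volume)."""


class AugmentationError(MvtsegError, RuntimeError):
    """Rigid augmentation could not keep the object inside the volume."""


class DivergenceError(MvtsegError, RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch, msg=None):
        super().__init__(msg or f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


class RecordError(MvtsegError, ValueError):
    """Crop record inconsistent with the data it is applied to."""
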