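"""Package-wide exception and warning types."""


class SpecmapError(Exception):
    """Base class for all specmap errors."""


class InvalidSelectionError(SpecmapError):
    """Atom/feature selection is unusable (e.g. fewer than two atoms)."""


class EmptyContactSpecError(SpecmapError):
    """No contact pairs survive the cutoff/sequence-separation filters."""


class DegenerateScaleError(SpecmapError):
    """Adaptive scale estimation failed (too many duplicated samples)."""


class DegenerateKernelError(SpecmapError):
    """Kernel matrix has a zero row sum; normalization undefined."""


class TrainingDivergedError(SpecmapError):
    """Non-finite gradient or objective encountered during training."""


class DisconnectedEndpointsError(SpecmapError):
    """Path endpoints are not connected through populated bins."""


class SpecmapWarning(UserWarning):
    """Base class for all specmap warnings."""


class KReductionWarning(SpecmapWarning):
    """Fewer distinct kinetic clusters found than requested."""


class NonImprovingWarning(SpecmapWarning):
    """Objective failed to improve over the whole training run."""
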