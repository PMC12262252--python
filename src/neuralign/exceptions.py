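"""Exception types shared across the package."""


class NeuralignError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(NeuralignError):
    """An input carries no usable signal (all-zero image, zero variance, ...)."""


class NoCorrespondenceError(NeuralignError):
    """Two ROI volumes share no common ROI indices."""


class CapacityError(NeuralignError):
    """More matched neurons than the fixed-size centroid list can hold."""


class ConfigurationError(NeuralignError):
    """Invalid or inconsistent configuration (empty grid, bad shape, ...)."""
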