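"""Exception hierarchy shared across the pipeline stages."""


class EpiclassError(Exception):
    """Base class for all package errors."""


class ConfigError(EpiclassError):
    """Invalid configuration: bad sampling rate, cutoff, counts, ..."""


class DegenerateInputError(EpiclassError):
    """Input too short, empty, or constant for the requested computation."""


class MonotoneResidualError(EpiclassError):
    """Too few extrema to build envelopes; the EMD residual is monotone."""


class StructuralError(EpiclassError):
    """Inconsistent shapes or schemas across a collection of inputs."""


class ContractError(EpiclassError):
    """Call violated an interface contract (length mismatch, missing features)."""


class SplitError(EpiclassError):
    """Train/test partition cannot satisfy the stratification contract."""


class SelectionError(EpiclassError):
    """Feature selection impossible (e.g. a single class in the training rows)."""


class EvaluationError(EpiclassError):
    """Metric undefined for the supplied predictions (e.g. one class only)."""
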