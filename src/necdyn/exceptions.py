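"""Exception hierarchy for necdyn."""


class NecdynError(Exception):
    """Base class for all necdyn errors."""


class StabilityError(NecdynError):
    """The state matrix is not Hurwitz-stable (no stationary regime exists)."""


class ConditioningError(NecdynError):
    """A linear solve is too ill-conditioned to trust."""


class ConsistencyError(NecdynError):
    """A (A, Sigma, S, sigma2) quadruple does not satisfy the decomposition identity."""


class SkewSymmetryError(NecdynError):
    """A matrix expected to be skew-symmetric is not, beyond tolerance."""


class DataError(NecdynError):
    """Input data are malformed (shapes, missing values, degenerate columns)."""


class InferenceError(NecdynError):
    """Model inversion failed (filter divergence, matrix-log domain, ...)."""
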