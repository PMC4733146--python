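"""Exception hierarchy shared across the package."""


class MultitraitError(Exception):
    """Base class for all package-specific errors."""


class StructuralError(MultitraitError, ValueError):
    """Malformed input structure: cyclic pedigree, unknown ids, rank-deficient designs."""


class DomainError(MultitraitError, ValueError):
    """Value outside the mathematical domain of an operation (e.g. non-PD covariance)."""


class DegenerateInputError(MultitraitError, ValueError):
    """Input that is formally valid but carries no usable information."""


class ConvergenceError(MultitraitError, RuntimeError):
    """An iterative procedure failed to converge after all fallbacks."""
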