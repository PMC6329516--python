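"""Exception hierarchy shared across the toolkit.

Exit-code mapping used by the CLI: ValidationError -> 2, SolverError -> 3.
"""


class ValidationError(ValueError):
    """Invalid inputs: inconsistent shapes, non-finite data, bad parameters."""


class SolverError(RuntimeError):
    """Iterative solver failure (divergence, non-finite iterate)."""


class UndefinedMetricError(ValidationError):
    """A metric is mathematically undefined for the given ROI (e.g. zero variance)."""
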