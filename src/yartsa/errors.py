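"""Typed exceptions raised across the package.

Every reader and analysis entry point raises one of these (never a bare
``ValueError`` from deep inside numpy) so callers can distinguish malformed
input from internal failure.
"""


class YartsaError(Exception):
    """Base class for all package errors."""


class NewickParseError(YartsaError):
    """Malformed Newick input (unbalanced parentheses, duplicate tips, ...)."""


class ValidationError(YartsaError):
    """A domain-type invariant is violated."""


class AlignmentError(YartsaError):
    """Ragged, empty or out-of-alphabet alignment input."""


class DistanceError(YartsaError):
    """A distance computation cannot be completed (no overlap, saturation...)."""


class AnalysisError(YartsaError):
    """An analysis precondition fails (label mismatch, zero variance, ...)."""


class ConfigError(YartsaError):
    """Invalid simulation or pipeline configuration."""


class SimulationError(YartsaError):
    """A stochastic simulation failed (e.g. repeated total extinction)."""
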