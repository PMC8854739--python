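"""Exception hierarchy shared across the pipeline stages."""


class TdafoldError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(TdafoldError, ValueError):
    """A caller-supplied argument violates a documented precondition."""


class GenerationError(TdafoldError, RuntimeError):
    """A synthetic-structure generator exhausted its retry budget."""


class DegenerateInputError(TdafoldError, ValueError):
    """A point cloud is too degenerate (collinear, too few points) to triangulate."""


class EmptyTrajectoryError(TdafoldError, ValueError):
    """An operation would leave a trajectory with no frames."""


class SolverError(TdafoldError, RuntimeError):
    """The exact 0/1 optimization for a volume-optimal cycle failed."""


class DegenerateFactorError(TdafoldError, ValueError):
    """A factor matrix contains an all-zero basis column and cannot be normalized."""


class ParseError(TdafoldError, ValueError):
    """A trajectory file could not be parsed; the message names the offending line."""
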