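"""Exception hierarchy shared across the package."""


class NetkitError(Exception):
    """Base class for all package-specific errors."""


class InvalidParametersError(NetkitError, ValueError):
    """Generator or model parameters outside their valid range."""


class DegenerateGraphError(NetkitError, ValueError):
    """Graph too small or otherwise degenerate for the requested statistic."""


class MissingNodeError(NetkitError, KeyError):
    """A referenced node is not present in the network."""


class EmptyInputError(NetkitError, ValueError):
    """An operation received an empty collection it cannot work with."""


class EmptyNetworkError(NetkitError, ValueError):
    """Network assembly produced no nodes (no seed matched any edge)."""


class ConflictingCategoryError(NetkitError, ValueError):
    """An accession is listed under two different node categories."""


class DegeneratePlantingError(InvalidParametersError):
    """Planted-partition probabilities do not separate modules (p_out >= p_in)."""


class InsufficientPointsError(NetkitError, ValueError):
    """Too few usable points for a regression fit."""


class InvalidCountsError(NetkitError, ValueError):
    """Hypergeometric contingency counts violate their bounds."""


class InvalidPValueError(NetkitError, ValueError):
    """A p-value outside [0, 1] was supplied."""


class CyclicOntologyError(NetkitError, ValueError):
    """The term parent relation contains a cycle."""


class BackgroundMismatchError(NetkitError, ValueError):
    """A study protein is absent from the enrichment background."""


class InvalidModeError(NetkitError, ValueError):
    """Unknown removal mode for the lethality test."""


class MissingSeedsError(NetkitError, ValueError):
    """Failure-mode lethality test called without random seeds."""


class IncompatibleTrajectoriesError(NetkitError, ValueError):
    """Robustness trajectories do not share the same initial network."""


class InvalidFormatError(NetkitError, ValueError):
    """Unknown network export format."""


class StageError(NetkitError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage:{stage}] {message}")
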