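"""Exception hierarchy for the RIN-states pipeline."""


class RinStatesError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RinStatesError):
    """Input files are inconsistent or not in a supported format."""


class TopologyError(RinStatesError):
    """The parsed structure cannot yield a valid residue topology."""


class GraphError(RinStatesError):
    """A graph operation's preconditions are violated (e.g. disconnected graph)."""


class DimensionError(RinStatesError):
    """Array shapes of two pipeline objects do not agree."""


class GenerationError(RinStatesError):
    """The synthetic-data generator was given an infeasible specification."""


class CapabilityError(RinStatesError):
    """A requested optional backend is not available."""
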