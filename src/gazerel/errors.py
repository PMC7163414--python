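"""Package exception hierarchy."""


class GazerelError(Exception):
    """Base class for package errors."""


class InputError(GazerelError, ValueError):
    """Malformed or out-of-contract input data (unsorted streams, etc.)."""


class SchemaError(GazerelError, ValueError):
    """Mismatch between data and a declared schema or item universe."""


class SimulationInfeasibleError(GazerelError, RuntimeError):
    """A session cannot be synthesized under the given configuration."""


class UndefinedAUROCError(GazerelError, ValueError):
    """AUROC requested for labels containing a single class."""
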