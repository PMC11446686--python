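"""Exception taxonomy.

Every error raised on a contract violation derives from :class:`NetswarmError`
so callers can catch the package's failures in one clause; each subclass also
derives from the closest builtin (``ValueError``, ``KeyError``, ...) so the
functions remain idiomatic when used outside the pipeline.
"""


class NetswarmError(Exception):
    """Base class for all netswarm errors."""


class ShapeError(NetswarmError, ValueError):
    """Array or argument dimensions are inconsistent."""


class CapacityError(NetswarmError, ValueError):
    """A request exceeds what the inputs can support (too many edges, too few samples/genes)."""


class TopologyError(NetswarmError, ValueError):
    """A network violates a structural requirement (e.g. contains a cycle)."""


class ParameterError(NetswarmError, ValueError):
    """A scalar parameter is outside its documented range."""


class DataError(NetswarmError, ValueError):
    """Input data violate a contract (non-finite values, empty arrays)."""


class DegenerateDataError(DataError):
    """Data are technically valid but leave the statistic undefined (zero variance everywhere)."""


class GeneLookupError(NetswarmError, KeyError):
    """A gene id, sample id, or group label is not present in the table."""


class PairingError(NetswarmError, ValueError):
    """Paired vectors have mismatched lengths."""


class TrainingDivergenceError(NetswarmError, RuntimeError):
    """Training loss became non-finite; the message names the epoch."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"training diverged (non-finite loss) at epoch {epoch}")


class FormatError(NetswarmError, ValueError):
    """A file does not conform to the expected text format."""


class InclusionError(NetswarmError, ValueError):
    """A dataset fails the inclusion filter (too few transcripts)."""


class ConfigError(NetswarmError, ValueError):
    """A pipeline configuration is invalid; the message names the offending key."""


class PipelineStageError(NetswarmError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
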