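"""Exception hierarchy for shankgait.

All errors derive from :class:`ShankGaitError` so callers can catch the
package's failures with a single except clause; the subclasses mirror the
failure modes of the pipeline stages (malformed files, out-of-range sensor
samples, bad configuration, insufficient events, ...).
"""


class ShankGaitError(Exception):
    """Base class for all shankgait errors."""


class FormatError(ShankGaitError, ValueError):
    """A file does not conform to the expected schema (missing columns...)."""


class DataError(ShankGaitError, ValueError):
    """Data violates an invariant (non-monotonic time, bad quaternions...)."""


class RangeError(DataError):
    """A sensor sample lies outside the physical range of the IMU."""


class ConfigError(ShankGaitError, ValueError):
    """Invalid pipeline configuration value."""


class SimulationError(ShankGaitError, ValueError):
    """Requested synthetic kinematics are infeasible (e.g. exceed sensor range)."""


class InsufficientDataError(ShankGaitError, ValueError):
    """Not enough events/samples to perform the requested computation."""


class AlignmentError(ShankGaitError, ValueError):
    """The two shank streams cannot be time-aligned."""


class PairingError(ShankGaitError, ValueError):
    """Two series/tables cannot be paired for comparison."""


class DegenerateDesignError(ShankGaitError, ValueError):
    """A statistic is undefined for this input (e.g. zero between-subject variance)."""
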