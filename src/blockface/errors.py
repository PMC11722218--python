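"""Exception hierarchy.

Physics preconditions (energy ranges, geometry) raise dedicated subclasses so
callers can distinguish a configuration mistake from a degenerate result
(e.g. no backscattered electrons at all).
"""


class BlockfaceError(Exception):
    """Base class for all package errors."""


class EnergyRangeError(BlockfaceError, ValueError):
    """Electron energy outside the validity range of a physics model."""


class GeometryError(BlockfaceError, ValueError):
    """Invalid or inconsistent specimen / detector / scan geometry."""


class DegenerateMaterialError(BlockfaceError, ValueError):
    """A material with zero density or otherwise unusable composition."""


class ContractError(BlockfaceError, ValueError):
    """An operation was fed an object that violates its precondition."""


class EmptyDistributionError(BlockfaceError, RuntimeError):
    """A requested distribution has no samples (e.g. no backscatter)."""


class NoPeakError(BlockfaceError, RuntimeError):
    """Profile analysis found no peak above the plateau noise."""


class NoSolutionError(BlockfaceError, ValueError):
    """An inversion has no solution in its admissible domain."""


class QuantificationError(BlockfaceError, RuntimeError):
    """A spectral quantification step failed (bad fit window, zero integral)."""


class StatisticsError(BlockfaceError, ValueError):
    """Too few samples/pixels for the requested statistic."""


class ConfigError(BlockfaceError, ValueError):
    """Configuration file failed schema validation; message names the key."""


class FileFormatError(BlockfaceError, ValueError):
    """A data file could not be parsed."""
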