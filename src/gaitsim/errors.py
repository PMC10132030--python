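"""Exception hierarchy.

Every error raised by the package derives from :class:`GaitSimError` and
carries a distinct process exit code used by the CLI.
"""


class GaitSimError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class FormatError(GaitSimError):
    """Malformed storage-file header or body."""

    exit_code = 10


class SamplingError(GaitSimError):
    """Non-uniform or otherwise invalid time base."""

    exit_code = 11


class InvalidRotationError(GaitSimError):
    """A stored matrix is not (close to) a proper rotation."""

    exit_code = 12


class UpsamplingLimitError(GaitSimError):
    """Requested resampling rate exceeds 10x the input rate."""

    exit_code = 13


class AttachmentError(GaitSimError):
    """Sensor placement references a different segment than the trajectory."""

    exit_code = 14


class GeometryError(GaitSimError):
    """Non-positive or inconsistent grid geometry."""

    exit_code = 20


class ConfigError(GaitSimError):
    """Invalid configuration values (e.g. shoe ring sizes)."""

    exit_code = 21


class UnsupportedGridError(GaitSimError):
    """Operation defined for leg grids only was given a shoe grid."""

    exit_code = 22


class InsufficientDataError(GaitSimError):
    """Too few samples for the requested numerical operation."""

    exit_code = 30


class AliasingError(GaitSimError):
    """Rotation increment per sample too large to differentiate."""

    exit_code = 31


class FilterError(GaitSimError):
    """Filter window/cutoff incompatible with the series."""

    exit_code = 32


class TrainingError(GaitSimError):
    """Threshold training found no candidate peaks."""

    exit_code = 40


class AlignmentError(GaitSimError):
    """Paired channels do not share a time base."""

    exit_code = 41


class BipedalInputError(GaitSimError):
    """A bilateral detector is missing its contralateral channel."""

    exit_code = 42


class UnsupportedCombinationError(GaitSimError):
    """Algorithm/phase-model combination not defined."""

    exit_code = 43


class NoStanceError(GaitSimError):
    """GRF trace contains no stance interval."""

    exit_code = 50


class InsufficientEventsError(GaitSimError):
    """Too few reference events for the requested statistic."""

    exit_code = 51


class StrategyError(GaitSimError):
    """Cross-validation strategy not applicable to the dataset."""

    exit_code = 52


class ScenarioError(GaitSimError):
    """Synthetic gait scenario parameters are infeasible."""

    exit_code = 60
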