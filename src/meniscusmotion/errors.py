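"""Exception hierarchy for the meniscal-motion pipeline.

Errors are grouped so that the command-line layer can map them to exit
codes: input/geometry problems (exit 2) versus solver convergence
failures (exit 3).
"""


class MeniscusMotionError(Exception):
    """Base class for all package errors."""


class InputError(MeniscusMotionError):
    """A required input file is missing or unreadable."""


class DimensionalityError(MeniscusMotionError):
    """An image does not have the expected 3D layout."""


class GeometryMismatchError(MeniscusMotionError):
    """Two objects that must share a voxel grid do not."""


class DegenerateInputError(MeniscusMotionError):
    """An input is formally valid but degenerate (e.g. an empty mask)."""


class DataError(MeniscusMotionError):
    """Non-finite or otherwise corrupt numeric data."""


class DegeneracyError(MeniscusMotionError):
    """A geometric construction is ill-posed (e.g. isotropic point cloud)."""


class TopologyError(MeniscusMotionError):
    """A mask does not have the topology an algorithm requires."""


class SpecError(MeniscusMotionError):
    """A phantom or cohort specification is self-inconsistent."""


class MotionError(MeniscusMotionError):
    """A synthetic motion model is invalid (e.g. non-invertible)."""


class InsufficientDataError(MeniscusMotionError):
    """Too few subjects/observations for the requested statistic."""


class PairingError(MeniscusMotionError):
    """Paired analysis requested but pairs are incomplete."""


class UndefinedTestError(MeniscusMotionError):
    """A statistical test is undefined for the given data (all-zero diffs)."""


class ConvergenceError(MeniscusMotionError):
    """An iterative solver failed to make progress.

    Carries the per-level objective trace (list of dict rows) so the
    failure can be inspected post mortem.
    """

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace if trace is not None else []
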