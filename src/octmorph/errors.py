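"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: :class:`DataError` (bad/missing/corrupt
inputs) exits with 3, :class:`AnalysisError` (a computation that could not
produce a result from valid inputs) exits with 4. Usage errors are handled by
click and exit with 2.
"""


class OctmorphError(Exception):
    """Base class for all package-specific errors."""


class DataError(OctmorphError):
    """Invalid, missing, or inconsistent input data."""


class ContainerError(DataError):
    """Malformed raw-fringe container file."""


class AnalysisError(OctmorphError):
    """An analysis step failed on otherwise valid inputs."""


class WallDetectionError(AnalysisError):
    """Ventricular wall edges could not be located in enough frames."""


class CycleDetectionError(AnalysisError):
    """Fewer than two complete cardiac cycles were found in the trace."""


class PeriodicityError(AnalysisError):
    """No dominant spectral peak: the diameter trace shows no periodicity."""


class StaleSidecarWarning(UserWarning):
    """The measurement sidecar's source digest no longer matches the source."""
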