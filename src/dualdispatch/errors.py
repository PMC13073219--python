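"""Exception types raised across the pipeline."""


class DualDispatchError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DualDispatchError, ValueError):
    """Invalid generator or run configuration."""


class PlacementError(DualDispatchError):
    """Station placement impossible (e.g. fewer distinct nodes than stations)."""


class SamplingError(DualDispatchError):
    """Event sampling impossible (e.g. all-zero density raster)."""


class RoutingError(DualDispatchError):
    """No route between two nodes, or nodes missing from the network."""


class CandidateError(DualDispatchError):
    """No candidate stations of the requested service."""


class PipelineError(DualDispatchError):
    """Missing intermediate results while assembling records."""


class StatsError(DualDispatchError):
    """Invalid input to a summary or test (empty records, n < 2, ...)."""


class FitError(StatsError):
    """Rank-deficient or otherwise unfittable model design."""


class ReportError(DualDispatchError):
    """Missing or inconsistent files while building a run report."""
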