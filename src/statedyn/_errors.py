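"""Exception hierarchy shared across the package."""


class StatedynError(Exception):
    """Base class for all statedyn errors."""


class FormatError(StatedynError):
    """Malformed input file (ragged rows, non-numeric cells, bad header)."""


class DesignError(StatedynError):
    """Study design violates requirements (non-rectangular, duplicates)."""


class ConfigurationError(StatedynError):
    """Invalid combination of options (e.g. missing symmetry map)."""


class DegenerateVolumeError(StatedynError):
    """A volume is constant across ROIs, so its spatial SD is zero."""


class InfeasibleKError(StatedynError):
    """Requested more clusters than distinct data rows."""


class ConvergenceError(StatedynError):
    """Iterative algorithm exceeded its iteration cap."""

    def __init__(self, message, best_objective=None):
        super().__init__(message)
        self.best_objective = best_objective


class DegenerateNDError(StatedynError):
    """ND denominator is zero (all within-participant pairs identical)."""
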