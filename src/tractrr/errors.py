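"""Exception hierarchy for the tractrr pipeline.

Every error raised deliberately by the package derives from :class:`TractrrError`
so callers (and the CLI) can distinguish pipeline failures from programming bugs.
"""


class TractrrError(Exception):
    """Base class for all tractrr errors."""


class ProtocolError(TractrrError):
    """Invalid or rank-deficient diffusion acquisition protocol."""


class PhantomError(TractrrError):
    """Degenerate phantom geometry (e.g. empty tract)."""


class SimulationError(TractrrError):
    """Invalid DWI simulation parameters."""


class CohortError(TractrrError):
    """Cohort generation failure (e.g. non-positive adjusted eigenvalues)."""


class MaskError(TractrrError):
    """Empty or grid-mismatched region-of-interest mask."""


class EmptyTractError(TractrrError):
    """A tract became empty after tracking or thresholding."""


class StatisticsError(TractrrError):
    """Undefined reliability statistic (zero variance, bad confidence level...)."""


class ConfigError(TractrrError):
    """Invalid study configuration."""
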