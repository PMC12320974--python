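"""Exception hierarchy for the heart-assay pipeline.

Every stage raises a subclass of :class:`FlyheartError` so batch drivers can
catch per-recording failures without masking programming errors.
"""


class FlyheartError(Exception):
    """Base class for all pipeline failures."""


class TooFewBeatsError(FlyheartError):
    """A recording (real or simulated) contains too few contraction events.

    Carries ``n_events`` so callers can report how many beats were found.
    """

    def __init__(self, message: str, n_events: int = 0):
        super().__init__(message)
        self.n_events = n_events


class NoMotionError(FlyheartError):
    """No periodic wall motion detectable (flat stack or trace)."""


class GeometryError(FlyheartError):
    """Simulated or measured geometry is inconsistent with the field of view."""


class OverlappingPulsesError(FlyheartError):
    """Two contraction pulses overlap in time; carries the offending pair."""

    def __init__(self, message: str, pair: tuple[int, int] | None = None):
        super().__init__(message)
        self.pair = pair


class DegenerateDataError(FlyheartError):
    """Input carries no usable variation (all values identical, all pairs tied...)."""


class ConfigError(FlyheartError):
    """Invalid run configuration or cohort design."""
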