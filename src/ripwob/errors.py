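"""Exception hierarchy for ripwob.

All domain errors derive from :class:`RipwobError` so callers (notably the
CLI) can convert any of them into a diagnostic message and a nonzero exit
code with a single ``except`` clause.
"""


class RipwobError(Exception):
    """Base class for all ripwob domain errors."""


class DegenerateWindowError(RipwobError, ValueError):
    """An analysis window carries too little signal for the requested index.

    Raised when both compartment excursions are below epsilon (flat window),
    when a channel has zero variance (phase undefined), or when the summed
    signal's excursion vanishes relative to the compartment excursions
    (unbounded LBI). The sliding-window pipeline catches this and emits an
    invalid sample instead of aborting the recording.
    """


class InsufficientDataError(RipwobError, ValueError):
    """A recording is shorter than one analysis window."""


class NoSpectralContentError(RipwobError, ValueError):
    """The restricted frequency band holds no usable spectral magnitude."""


class RecordingParseError(RipwobError, ValueError):
    """A recording file violates the expected CSV contract."""


class UnknownPresetError(RipwobError, KeyError):
    """Requested synthetic preset name is not defined."""
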