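"""Exception hierarchy for the vchopper package."""


class VChopperError(Exception):
    """Base class for all vchopper errors."""


class InvalidConfigError(VChopperError, ValueError):
    """An acquisition configuration violates a structural invariant."""


class UnsupportedCombinationError(VChopperError, ValueError):
    """A frame-rate / pulse-frequency pair cannot be rationalized."""


class InfeasibleSettingsError(VChopperError, ValueError):
    """No acquisition setting satisfies the timing rules."""


class NoGatingError(VChopperError, ValueError):
    """No UV-on -> UV-off transition found in the label sequence."""


class DriftEstimateError(VChopperError, ValueError):
    """Frame-rate drift could not be estimated from gated intensities."""


class InsufficientSamplesError(VChopperError, ValueError):
    """Too few gated frames to form a decay sequence or fit."""


class FormatError(VChopperError, ValueError):
    """Frame stack on disk is malformed (mixed shapes, missing frames...)."""
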