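"""Exception hierarchy for panel validation and orbit consistency failures."""


class OrbitPanelError(ValueError):
    """Base class for all orbitpanel validation errors."""


class DimensionError(OrbitPanelError):
    """Mismatched variable counts, prefix lengths, or state sizes."""


class SizeError(OrbitPanelError):
    """Requested state-space size outside the enumerable range."""


class BoundsError(OrbitPanelError):
    """State index outside [1, 2^p * p!]."""


class CodingError(OrbitPanelError):
    """Non-binary value encountered where 0/1 coding is required."""


class CompletenessError(OrbitPanelError):
    """Missing observations in a panel that requires complete data."""


class StratificationError(OrbitPanelError):
    """Stratification attribute is not constant within a subject."""


class OrbitCorruptionError(OrbitPanelError):
    """Consecutive orbit states are not related by the transition rule."""
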