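class OxlandError(Exception):
    """Base class for all package errors."""


class SimulationError(OxlandError):
    """A synthetic-data generator could not satisfy its contract."""


class TrackError(OxlandError):
    """Mismatched tilings or malformed binned tracks."""
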