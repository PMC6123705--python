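"""Exception hierarchy for the enoe package."""


class ENOEError(Exception):
    """Base class for all enoe-specific errors."""


class FormatError(ENOEError):
    """Malformed input: PDB streams, buildup tables, restraint files."""


class NameNormalizationError(FormatError):
    """A hydrogen atom-name dialect that cannot be mapped to PDB v3."""


class GeometryError(ENOEError):
    """Physically impossible geometry (e.g. overlapping protons)."""


class FitError(ENOEError):
    """A fit could not be performed at all (empty or unusable series)."""
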