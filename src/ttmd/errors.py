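"""Exception hierarchy for the TTMD toolkit."""


class TTMDError(Exception):
    """Base class for all toolkit errors."""


class FormatError(TTMDError):
    """Malformed input file (duplicate serials, unparseable records...)."""


class SelectorError(TTMDError):
    """An atom/residue selection matched nothing or was ill-formed."""


class GeometryError(TTMDError):
    """Degenerate geometry (collinear or coincident superposition set...)."""


class ConfigurationError(TTMDError):
    """Invalid run configuration or an all-zero reference fingerprint."""


class ParameterError(TTMDError):
    """Missing per-atom force-field parameters for an energy calculation."""


class UsageError(TTMDError):
    """An operation called with arguments outside its domain."""
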