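"""Exception hierarchy shared across the package."""


class InbredQTLError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(InbredQTLError, ValueError):
    """An argument is outside its documented domain."""


class StructuralError(InbredQTLError, ValueError):
    """Inputs are individually valid but mutually inconsistent."""


class DegeneratePanelError(InbredQTLError, ValueError):
    """A generated panel would be monomorphic or otherwise unusable."""


class DegenerateComponentError(InbredQTLError, ValueError):
    """A required variance component has zero empirical variance."""


class KinshipEstimationError(InbredQTLError, ValueError):
    """Kinship cannot be estimated, e.g. no jointly observed SNPs for a pair."""


class ConfigurationError(InbredQTLError, ValueError):
    """An analysis configuration is inconsistent with the data."""


class ParseError(InbredQTLError, ValueError):
    """A file does not conform to its documented dialect."""
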