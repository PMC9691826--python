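"""Exception types shared across pedrisk modules."""


class PedriskError(Exception):
    """Base class for all pedrisk errors."""


class ConfigError(PedriskError):
    """A model configuration file or parameter table failed validation."""


class PedigreeError(PedriskError):
    """A pedigree file or structure failed validation."""


class ModelError(PedriskError):
    """A model computation was requested on inconsistent or degenerate inputs."""


class ConvergenceError(PedriskError):
    """An iterative numerical procedure failed to reach its tolerance."""
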