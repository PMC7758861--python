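"""Exception hierarchy shared across the pipeline stages."""


class FormhaemError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FormhaemError):
    """A scenario or pipeline configuration violates its invariants."""


class GenerationError(FormhaemError):
    """A synthetic-data generator could not satisfy its post-conditions."""


class InputError(FormhaemError):
    """An analysis operation received inputs violating its pre-conditions."""
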