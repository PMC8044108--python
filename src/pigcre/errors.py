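"""Exception types shared across the pipeline."""


class PigcreError(Exception):
    """Base class for pipeline errors."""


class SizingError(PigcreError, ValueError):
    """A genome is too small for what was requested to be placed on it."""


class ConfigurationError(PigcreError, ValueError):
    """A parameter combination that cannot produce a usable simulation."""


class CoordinateError(PigcreError, ValueError):
    """An interval falls outside its chromosome or violates ordering."""


class InputError(PigcreError, ValueError):
    """Malformed or inconsistent input data."""
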