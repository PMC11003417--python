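"""Exception hierarchy shared across the package."""


class SaavBenchError(Exception):
    """Base class for all saavbench errors."""


class InputError(SaavBenchError, ValueError):
    """Malformed or missing input data (sequences, tables, files)."""


class ConfigError(SaavBenchError, ValueError):
    """Invalid configuration: missing columns, bad paths, bad parameters."""


class InvalidSubstitutionError(InputError):
    """A substitution was requested between identical residue classes."""
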