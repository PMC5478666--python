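class EndomethylError(Exception):
    """Base class for pipeline errors."""


class ConfigError(EndomethylError):
    """Invalid configuration value."""


class ValidationError(EndomethylError):
    """Invalid input data (negative intensities, unpaired subjects, ...)."""


class GenerationError(EndomethylError):
    """Synthetic-data generation could not satisfy its constraints."""
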