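"""Exception hierarchy shared by all morfmlp modules."""


class MorfMlpError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(MorfMlpError):
    """A file does not conform to its expected on-disk format."""


class AlignmentError(MorfMlpError):
    """A profile or annotation does not line up with its sequence."""


class ConfigurationError(MorfMlpError):
    """An invalid combination of parameters was supplied."""


class TrainingError(MorfMlpError):
    """Model training cannot proceed or diverged."""


class EvaluationError(MorfMlpError):
    """Metrics cannot be computed for the given predictions/labels."""
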