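"""Exception hierarchy for configuration, input, and file-format errors."""


class ConsensomeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ConsensomeError):
    """A configuration value is out of range or an unknown key was supplied."""


class InputError(ConsensomeError):
    """An in-memory input violates a precondition (sets outside universe, ...)."""


class SchemaError(ConsensomeError):
    """A file does not match the expected column schema."""


class IntegrityError(ConsensomeError):
    """A file parses but violates an integrity constraint (duplicate ids, ...)."""
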