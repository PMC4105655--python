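class ParameterError(ValueError):
    """A parameter violates a documented precondition."""


class FormatError(ValueError):
    """A file could not be parsed in the expected format."""
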