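"""Exception types shared across the package."""


class InvalidConfigError(ValueError):
    """A configuration value violates a documented invariant."""


class ParseError(ValueError):
    """A data file could not be parsed; the message names file and line/field."""
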