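"""Package exceptions."""


class InputError(ValueError):
    """Invalid argument or model configuration."""


class FormatError(ValueError):
    """Malformed input file."""


class InvalidTetradError(ValueError):
    """A tetrad pattern violating 2:2 segregation or the three-locus scheme."""
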