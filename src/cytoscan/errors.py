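"""Package-level exception types."""


class InputError(ValueError):
    """Raised for malformed, inconsistent or missing input data."""
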