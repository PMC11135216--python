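"""Package-level exception types."""


class DataError(ValueError):
    """Input data violates a contract (non-finite sample, non-monotone time,
    empty result, malformed row)."""


class FormatError(ValueError):
    """A file is not a valid artifact of this package (wrong magic, version,
    or truncated)."""
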