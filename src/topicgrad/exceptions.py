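"""Exception hierarchy.

``ValidationError`` flags inputs that violate a documented contract
(negative counts, mismatched vocabularies, out-of-range parameters);
``FormatError`` flags files that cannot be parsed as the declared format.
Both derive from ``ValueError`` so callers can catch broadly.
"""


class TopicgradError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(TopicgradError, ValueError):
    """An input value violates a documented precondition or invariant."""


class FormatError(TopicgradError, ValueError):
    """A file does not conform to its declared on-disk format."""
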