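"""Exception hierarchy.

``UsageError`` signals a bad configuration or invocation; ``DataError``
signals inputs that fail their contracts.  The CLI maps them to exit
codes 1 and 2 respectively.
"""


class TidelineError(Exception):
    """Base class for all package errors."""


class UsageError(TidelineError):
    """Invalid configuration, option, or invocation."""


class DataError(TidelineError, ValueError):
    """Input data violates a precondition (negative counts, missing sample...)."""
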