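"""Exception hierarchy.

Everything raised on bad user input derives from :class:`EcocladeError`
so the CLI can map domain failures to a single exit code.
"""


class EcocladeError(ValueError):
    """Base class for all user-facing errors."""


class TreeError(EcocladeError):
    """Malformed newick, unknown node ids, undefined rooting, etc."""


class TableError(EcocladeError):
    """Malformed or inconsistent OTU tables / metadata."""
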