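"""Exception hierarchy.

All package-specific failures derive from :class:`SigmatchError` so callers
(and the CLI) can distinguish configuration problems (exit code 2) from
data/algorithm problems (exit code 1).
"""


class SigmatchError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(SigmatchError, ValueError):
    """Invalid configuration or arguments; names the violated invariant."""


class FormatError(SigmatchError, ValueError):
    """Malformed input file; message names the file (and line where known)."""


class ValidationError(SigmatchError, ValueError):
    """Input data violates a type invariant (duplicates, coverage, sizes)."""


class AlgorithmError(SigmatchError, RuntimeError):
    """A precondition of an analysis step does not hold."""


class SelectionError(AlgorithmError):
    """No candidate clustering satisfies the selection criterion."""
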