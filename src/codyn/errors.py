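"""Exception hierarchy.

``InputError`` maps to CLI exit code 2 (malformed or inconsistent input),
``AnalysisError`` to exit code 3 (convergence / analysis failures).
"""


class CodynError(Exception):
    """Base class for all package errors."""


class InputError(CodynError):
    """Malformed or internally inconsistent input data."""

    exit_code = 2


class AnalysisError(CodynError):
    """A computation could not be completed (non-convergence, degenerate data)."""

    exit_code = 3
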