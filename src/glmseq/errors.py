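"""Exception hierarchy.

All package-raised errors derive from :class:`GlmseqError` so callers (and
the CLI) can distinguish bad input (exit status 1) from runtime failures
(exit status 2).
"""


class GlmseqError(Exception):
    """Base class for all glmseq errors."""


class InvalidInputError(GlmseqError, ValueError):
    """Raised when user-supplied data violates a precondition."""


class ConvergenceError(GlmseqError, RuntimeError):
    """Raised when IRLS fails to converge on non-degenerate input.

    Carries iteration diagnostics in :attr:`n_iter` and
    :attr:`last_change`.
    """

    def __init__(self, message: str, n_iter: int, last_change: float):
        super().__init__(message)
        self.n_iter = n_iter
        self.last_change = last_change
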