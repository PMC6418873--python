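"""Exception hierarchy shared across the package."""


class DomainError(ValueError):
    """An input violates a documented precondition or invariant."""


class TrainingError(RuntimeError):
    """Optimization failed (non-finite cost, divergence)."""
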