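"""Exception hierarchy.

All model-level failures derive from :class:`DomainError` so callers can
distinguish bad inputs from programming errors.
"""


class DomainError(ValueError):
    """An input violates a precondition of the pricing model."""


class PatentExpiredError(DomainError):
    """Evaluation year lies at or beyond patent expiry: no price is defined."""


class UnpriceableError(DomainError):
    """The eligible patient population is empty, the amortization diverges."""


class InfeasibleSpecError(DomainError):
    """A synthetic-profile specification cannot be satisfied."""
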