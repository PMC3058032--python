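"""Exception hierarchy shared by every seqfab module."""

from __future__ import annotations


class SeqFabError(Exception):
    """Base class for all seqfab errors."""


class ValidationError(SeqFabError):
    """Input data violates a rule; carries the full list of violations.

    ``violations`` is a list of human-readable messages (one per offending
    field or row) so a caller can report every problem at once.
    """

    def __init__(self, message: str, violations: list[str] | None = None):
        super().__init__(message)
        self.violations: list[str] = list(violations or [])

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        base = super().__str__()
        if self.violations:
            return base + "\n  - " + "\n  - ".join(self.violations)
        return base


class StateError(SeqFabError):
    """An operation was attempted in a lifecycle state that forbids it."""


class CapacityError(SeqFabError):
    """A plate or spreadsheet capacity limit was exceeded."""

    def __init__(self, message: str, overflow: int = 0):
        super().__init__(message)
        self.overflow = overflow


class AuthorizationError(SeqFabError):
    """The acting principal lacks the role or group access required."""


class SheetError(SeqFabError):
    """An uploaded sheet or archive does not match the run it targets."""
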