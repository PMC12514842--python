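"""Exception hierarchy.

Every error raised by this package derives from :class:`TriadgeoError` so
callers (and the CLI) can catch one base class and still report the module
that failed.
"""

from __future__ import annotations


class TriadgeoError(Exception):
    """Base class for all package errors."""


class ParseError(TriadgeoError):
    """A coordinate file could not be parsed; message carries path context."""


class FormatError(TriadgeoError):
    """Unknown or undeclared coordinate format."""


class MissingAtomError(TriadgeoError):
    """One or more selected atoms could not be resolved.

    Attributes
    ----------
    missing : list of (ResidueRef, str)
        Every unresolved (residue, atom-name) pair, not just the first.
    """

    def __init__(self, missing, context: str = ""):
        self.missing = list(missing)
        pairs = ", ".join(f"{ref}:{name}" for ref, name in self.missing)
        msg = f"unresolved atoms: {pairs}"
        if context:
            msg = f"{context}: {msg}"
        super().__init__(msg)


class GeometryError(TriadgeoError):
    """Degenerate geometry (too few points, collinear sets, ...)."""


class PairingError(TriadgeoError):
    """Chains of two models could not be paired."""


class ValidationError(TriadgeoError):
    """Invalid user input (configs, manifests, parameters)."""


class FitError(TriadgeoError):
    """A statistical fit could not be performed (degenerate data)."""
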