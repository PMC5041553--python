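"""Exception hierarchy shared across the package."""


class EsalignError(Exception):
    """Base class for all package-specific errors."""


class InputError(EsalignError):
    """Unreadable or malformed input."""


class EmptyStructureError(InputError):
    """A PDB source with no ATOM records."""


class SelectionError(EsalignError):
    """Requested model or chain does not exist; message names what is available."""


class DegenerateChainError(EsalignError):
    """Fewer than two valid residues after backbone validation."""


class DegenerateCurveError(EsalignError):
    """A curve with zero total spatial length or zero SRVF norm."""


class PropertyLookupError(EsalignError):
    """Residue code not mappable to a standard amino acid in strict mode."""


class ContractError(EsalignError):
    """An internal pre-condition was violated (grid mismatch, bad dimensions...)."""


class RunError(EsalignError):
    """Too many pairwise failures in a batch computation."""
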