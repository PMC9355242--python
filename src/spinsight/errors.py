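"""Exception hierarchy shared across the package."""


class SpinsightError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(SpinsightError):
    """Raised when a PDB text cannot be parsed into a structure."""


class AddressError(SpinsightError, KeyError):
    """Raised when a (chain, residue, atom) address does not resolve."""


class UnsupportedResidueError(SpinsightError):
    """Raised when an operation cannot be applied to a residue type (e.g. Gly)."""


class BuriedSiteError(SpinsightError):
    """Raised when no clash-free label conformer can be placed at a site."""


class EmptySelectionError(SpinsightError):
    """Raised when an atom selector matches nothing."""


class GridRangeError(SpinsightError):
    """Raised when a distance grid does not span the observed distances."""


class BackgroundFitError(SpinsightError):
    """Raised when the intermolecular background fit yields an invalid modulation depth."""


class InversionError(SpinsightError):
    """Raised when the constrained Tikhonov solver fails to converge."""


class PairingError(SpinsightError):
    """Raised when two intensity tables share no residues."""


class CoverageError(SpinsightError):
    """Raised when required per-residue inputs (e.g. distances) are missing."""


class SelfComparisonError(SpinsightError):
    """Raised when a residue is tested against a reference set containing itself."""


class FetchError(SpinsightError):
    """Raised when an external input (PDB entry, deposited dataset) cannot be retrieved."""
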