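"""Exception hierarchy.

All package errors derive from :class:`EnmRemdError` so callers (and the
CLI) can catch one base class and turn it into a one-line diagnostic.
"""


class EnmRemdError(Exception):
    """Base class for all errors raised by this package."""


class StructureParseError(EnmRemdError):
    """PDB text could not be reduced to a valid Cα model."""


class StructureFormatError(EnmRemdError):
    """Structurally valid file violating a contract (e.g. duplicate CA)."""


class DegenerateStructureError(EnmRemdError):
    """An operation produced or received an empty/unusable structure."""


class ConfigurationError(EnmRemdError):
    """Invalid configuration value or domain-range definition."""


class PartitionError(EnmRemdError):
    """Domain partition inconsistent with the structure (e.g. empty domain)."""


class GeometryError(EnmRemdError):
    """Degenerate geometry: coincident centroids, collinear selections, ..."""


class NumericalError(EnmRemdError):
    """Eigensolver failure or non-physical eigenvalues among selected modes."""


class IntegrationError(EnmRemdError):
    """Dynamics blew up (non-finite energy/coordinates), names the step."""
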