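"""Exception hierarchy for eemkit.

All package errors derive from :class:`EEMKitError` so callers can catch one
base class at tool boundaries (the CLI does exactly that).
"""


class EEMKitError(Exception):
    """Base class for all eemkit errors."""


class FormatError(EEMKitError):
    """Unknown or malformed structure / charge / parameter file."""


class ElementError(EEMKitError):
    """An atom's chemical element could not be recognized or inferred."""


class EmptyInputError(EEMKitError):
    """An operation received an empty molecule or value set."""


class DimensionError(EEMKitError):
    """Mismatched lengths, e.g. charges vs. atoms."""


class ParameterValidationError(EEMKitError):
    """Parameter-set XML violates the schema or value constraints."""


class MissingParameterError(EEMKitError):
    """A requested atom type is absent from a parameter set."""


class ApplicabilityError(EEMKitError):
    """Parameter set does not cover the molecule's atom types."""


class DegenerateGeometryError(EEMKitError):
    """Two atoms (nearly) coincide, making the EEM coupling singular."""


class EEMNumericalError(EEMKitError):
    """The EEM system is singular or could not be solved accurately."""


class InvalidDeprotonationError(EEMKitError):
    """Attempt to remove a non-hydrogen atom as an acidic proton."""


class DescriptorError(EEMKitError):
    """A QSPR descriptor required by a model is missing."""


class CollinearityError(EEMKitError):
    """QSPR design matrix is rank deficient."""


class PackingError(EEMKitError):
    """Synthetic globule generation could not satisfy the minimum separation."""


class ConfigError(EEMKitError):
    """Invalid CLI/job configuration."""
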