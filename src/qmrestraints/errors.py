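"""Exception hierarchy."""


class QmrError(Exception):
    """Base class for all package errors."""


class FormatError(QmrError):
    """Unparseable input (names the offending line or loop)."""


class SerializationError(QmrError):
    """Model cannot be represented in the requested output format."""


class ConfigurationError(QmrError):
    """Invalid cell, unknown space group, or inconsistent options."""


class SelectionError(QmrError):
    """A ligand selector matched zero or more than one residue."""


class ValidationError(QmrError):
    """Chemically inconsistent input (e.g. a water with three protons)."""


class GenerationError(QmrError):
    """Restraint-target generation failed (missing roster coordinates)."""


class InternalConsistencyError(QmrError):
    """A cluster operation was applied to an already-modified cluster."""


class BackendUnavailableError(QmrError):
    """The requested external optimization engine is not configured."""


class OptimizationError(QmrError):
    """The builtin minimizer aborted (e.g. exploding gradient)."""


class UndefinedTorsionError(QmrError):
    """Torsion requested over collinear atoms."""
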