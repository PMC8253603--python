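"""Exception hierarchy for structmat.

All package-raised errors derive from :class:`StructmatError` so callers (and
the CLI) can distinguish domain failures from programming errors.
"""


class StructmatError(Exception):
    """Base class for all structmat domain errors."""


class ChainNotFoundError(StructmatError):
    """A named chain is absent from the structure."""


class TopologyMismatchError(StructmatError):
    """Frames of one ensemble differ in atom count or ordering."""


class CoreBoundsError(StructmatError):
    """The 9-mer core window falls outside the peptide sequence."""


class FormatError(StructmatError):
    """Input or output violates the expected file format."""


class ParameterError(StructmatError):
    """An operation received an out-of-range parameter."""


class MissingDataError(StructmatError):
    """Required data (e.g. per-frame energies) are absent."""


class NormalizationError(StructmatError):
    """Observable accumulation cannot be normalized consistently."""


class AlphabetError(StructmatError):
    """A sequence contains a non-standard amino-acid letter."""


class CapacityError(StructmatError):
    """A synthetic-data request exceeds the generator's geometric capacity."""


class ValidationError(StructmatError):
    """A domain object violates one of its invariants."""
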