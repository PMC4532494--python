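"""Exception hierarchy used across the package."""


class SdmPhyloError(Exception):
    """Base class for all package errors."""


class InputError(SdmPhyloError):
    """Missing, unparseable or out-of-contract input."""


class LookupError_(SdmPhyloError):
    """A requested chain or label does not exist."""


class DegenerateInputError(SdmPhyloError):
    """Input too small or too degenerate for the operation (< 3 points etc.)."""


class FormatError(SdmPhyloError):
    """A structured text file violates its documented format."""


class ConsistencyError(SdmPhyloError):
    """Internally inconsistent quantities (e.g. more equivalences than residues)."""


class CompletenessError(SdmPhyloError):
    """A required set of items (e.g. all unordered pairs) is incomplete."""


class GenerationError(SdmPhyloError):
    """The synthetic-data generator cannot satisfy its own constraints."""
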