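"""Exception hierarchy.

Grouped so the command-line layer can map error families onto distinct
exit codes (config, format, generation/degeneracy).
"""


class D4RefitError(Exception):
    """Base class for all package errors."""


class MalformedFileError(D4RefitError):
    """A structured input file (XYZ, TSV table) violates its format."""


class CompositionError(D4RefitError):
    """A structure does not have water stoichiometry (2 H per O)."""


class PartitionError(D4RefitError):
    """Atoms could not be partitioned into intact water monomers."""


class ParameterError(D4RefitError):
    """A dispersion parameter file is missing or inconsistent."""


class DataError(D4RefitError):
    """Energy/component records are missing, mismatched or degenerate."""


class GenerationError(D4RefitError):
    """Synthetic-cluster placement failed under the given constraints."""


class ValidationWarning(UserWarning):
    """Non-fatal data-quality issue (recorded, processing continues)."""
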