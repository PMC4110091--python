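"""Exception hierarchy for lineage parsing, validation and sampling."""


class LineageError(ValueError):
    """Base class for all linrob errors."""


class NewickParseError(LineageError):
    """The Newick text could not be parsed."""


class StructureError(LineageError):
    """The tree violates the rooted-binary lineage invariants."""


class MappingError(LineageError):
    """A terminal cell is missing from (or inconsistent with) a mapping."""


class DegenerateInputError(LineageError):
    """The input is too small or too uniform for the statistic to exist."""


class ConstraintError(LineageError):
    """A constrained randomization could not satisfy its constraints."""
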