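"""Exception hierarchy.

All package-specific failures derive from :class:`LipidRegNetError` so callers
can catch one base class. Parse- and validation-type errors additionally
derive from :class:`ValueError` for ergonomic use in scripts.
"""


class LipidRegNetError(Exception):
    """Base class for all lipidregnet errors."""


class UnknownLipidClass(LipidRegNetError, ValueError):
    """Species name carries a class token outside the controlled vocabulary."""


class MalformedSpecies(LipidRegNetError, ValueError):
    """Species name does not tokenize as ``CLASS C:D[(a:b/...)]``."""


class InconsistentChains(LipidRegNetError, ValueError):
    """Resolved acyl chains do not sum to the species totals."""


class EmptyInput(LipidRegNetError, ValueError):
    """An operation received an empty table or profile set."""


class DegenerateScope(LipidRegNetError, ValueError):
    """A mol%% / DBI denominator scope has zero total amount or no members."""


class UnresolvedChains(LipidRegNetError, ValueError):
    """Fatty-acid composition requested for species without resolved chains."""


class InsufficientReplicates(LipidRegNetError, ValueError):
    """A group test received a group with fewer than two values."""


class MissingBaseline(LipidRegNetError, ValueError):
    """No control-condition Ct observations at a required timepoint."""


class MissingReference(LipidRegNetError, ValueError):
    """No reference-gene Ct observation for a (condition, timepoint, replicate)."""


class AmbiguousRecord(LipidRegNetError, ValueError):
    """Duplicate log2FC records for one (gene, condition, timepoint)."""


class MalformedRecord(LipidRegNetError, ValueError):
    """A differential-expression record violates its field contracts."""


class UndefinedCorrelation(LipidRegNetError, ValueError):
    """Pearson correlation requested against a constant vector."""


class GridMismatch(LipidRegNetError, ValueError):
    """TF and gene profile tables are not on the same (condition, time) grid."""


class SpecError(LipidRegNetError, ValueError):
    """A simulation specification violates its invariants."""


class InputError(LipidRegNetError, ValueError):
    """An input table is unreadable or malformed (with row-level context)."""
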