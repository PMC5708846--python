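"""Exception hierarchy.

Every anticipated domain failure raises a subclass of :class:`PocketforgeError`
so callers (and the CLI) can distinguish bad input from genuine bugs.
"""


class PocketforgeError(Exception):
    """Base class for all anticipated errors."""


class FormatError(PocketforgeError):
    """Unparseable structure or table input."""


class SelectorError(PocketforgeError):
    """A ligand / entity selector matched zero or several entities."""


class EmptyPocketError(PocketforgeError):
    """Pocket definition produced no residues (bad seed or cutoff)."""


class MappingError(PocketforgeError):
    """A Ballesteros-Weinstein anchor could not be resolved."""


class AnnotationError(PocketforgeError):
    """Topology annotation does not cover the receptor."""


class CorrespondenceError(PocketforgeError):
    """Residue lists of two objects being compared do not match."""


class DimensionError(PocketforgeError):
    """Vector / matrix shapes incompatible."""


class RankingError(PocketforgeError):
    """A model is missing a score required for ranking."""


class ClassError(PocketforgeError):
    """A required compound class is absent from a screening table."""


class DataError(PocketforgeError):
    """Malformed screening-table record."""


class IdError(PocketforgeError):
    """An identifier was not found."""


class MoleculeError(PocketforgeError):
    """A molecule could not be processed (parsing, fingerprinting)."""


class SpecError(PocketforgeError):
    """A synthetic-fixture specification is infeasible."""


class ConfigError(PocketforgeError):
    """Invalid run configuration."""


class BackendError(PocketforgeError):
    """A pluggable refinement backend failed."""
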