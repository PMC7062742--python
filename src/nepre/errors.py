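"""Exception hierarchy for the nepre package.

All package-specific failures derive from :class:`NepreError` so callers can
catch one base class at tool boundaries.
"""


class NepreError(Exception):
    """Base class for all nepre errors."""


class PDBParseError(NepreError):
    """A PDB file could not be parsed (malformed fixed-column record)."""


class EmptyStructureError(NepreError):
    """A structure file yielded no usable protein residues."""


class DegenerateResidueError(NepreError):
    """A residue has no heavy atoms, so its geometric center is undefined."""


class IncompleteBackboneError(NepreError):
    """A residue lacks the N or CA atom needed for the local frame."""


class DegenerateFrameError(NepreError):
    """Local-frame construction hit collinear or coincident geometry."""


class EmptyModelError(NepreError):
    """Statistics were requested from a model with zero counts."""


class ZeroCountError(NepreError):
    """Energy derivation with pseudocount 0 encountered an empty angular bin."""


class ScoreUndefinedError(NepreError):
    """A structure has no scoreable residues (distinct from energy 0)."""


class IncompatibleModelError(NepreError):
    """A persisted model does not match the expected grid/scheme/version."""


class FixtureSpecError(NepreError):
    """A synthetic-fixture specification is internally inconsistent."""
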