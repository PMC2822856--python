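"""Exception hierarchy for mhc2struct."""


class Mhc2StructError(Exception):
    """Base class for all package errors."""


class ParseError(Mhc2StructError):
    """A PDB or table file could not be parsed."""


class EmptyStructureError(Mhc2StructError):
    """Parsing retained no standard amino-acid residues."""


class ReductionError(Mhc2StructError):
    """A residue could not be reduced to a centroid."""


class InputError(Mhc2StructError):
    """Invalid argument values (sizes, ranges, schemes...)."""


class InfeasibleGeometryError(Mhc2StructError):
    """A synthetic-structure request cannot be satisfied geometrically."""
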