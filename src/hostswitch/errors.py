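"""Exception hierarchy shared by all stages."""


class HostswitchError(Exception):
    """Base class for all package errors."""


class SchemaError(HostswitchError):
    """An input table is missing required columns."""


class ValidationError(HostswitchError):
    """A field value violates a type invariant (e.g. abundance < 1)."""


class ReferentialError(HostswitchError):
    """A record references an unknown host/taxon, or duplicates a pair."""


class NewickParseError(HostswitchError):
    """Malformed Newick input (unbalanced parentheses, duplicate labels)."""


class TreeStructureError(HostswitchError):
    """Tree violates structural requirements (polytomy, unifurcation)."""


class AlignmentError(HostswitchError):
    """Sequences in a FASTA alignment differ in length."""


class AlphabetError(HostswitchError):
    """A sequence contains characters outside {A, C, G, T, -, N}."""


class EvidenceError(HostswitchError):
    """Contradictory or impossible classification evidence."""


class CoverageError(HostswitchError):
    """Evidence or category assignments do not cover every taxon."""


class SaturationError(HostswitchError):
    """Observed divergence outside the domain of the K2P logarithms."""


class NoOverlapError(HostswitchError):
    """No comparable (non-gap, non-N) sites between two sequences."""


class PhiError(HostswitchError):
    """Leaf association map is not total or maps outside the host leaves."""


class SimulationError(HostswitchError):
    """A simulator could not produce a valid replicate."""


class StageError(HostswitchError):
    """A pipeline stage failed; message names the stage and offending item."""
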