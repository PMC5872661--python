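"""Exception hierarchy.

Usage errors (bad invocation / config) and data errors (inputs that parse
but violate a contract) are kept distinct so the CLI can map them to the
documented exit codes.
"""


class PlastmineError(Exception):
    """Base class for all package errors."""


class UsageError(PlastmineError):
    """Invalid invocation: missing inputs, contradictory options."""


class DataError(PlastmineError):
    """Well-formed input that violates a data contract."""


class AmbiguousStructureError(DataError):
    """Multiple non-nested inverted-repeat pairs of equal maximal length."""

    def __init__(self, candidates):
        self.candidates = list(candidates)
        super().__init__(
            "ambiguous quadripartite structure; candidate IR pairs of equal "
            f"maximal length: {self.candidates}"
        )


class AnchorCollisionError(DataError):
    """Two same-class SSR loci of one genotype map to one alignment anchor."""

    def __init__(self, loci):
        self.loci = list(loci)
        super().__init__(f"SSR anchor collision between loci: {self.loci}")


class SimulationError(PlastmineError):
    """Rejection sampling or event placement exhausted its retry budget."""
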