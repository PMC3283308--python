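"""Exception types raised across the package."""


class DedoubleError(Exception):
    """Base class for all package errors."""


class ParseError(DedoubleError):
    """Malformed genome or scenario text."""


class NotDedoubledError(DedoubleError):
    """Operation requires a dedoubled genome (every couple adjacent as (x x') or (x' x))."""


class MissingKeyError(DedoubleError):
    """Ancestor expansion key absent from the genome."""


class AdjacencyNotFound(DedoubleError):
    """A cut refers to an adjacency that is not present in the genome."""


class IdenticalCuts(DedoubleError):
    """A DCJ must cut two *different* adjacencies."""


class InvalidRejoin(DedoubleError):
    """The new adjacencies of an operation do not repartition the exposed extremities."""


class CutsOnDifferentChromosomes(DedoubleError):
    """A reversal must cut two adjacencies of a single chromosome."""


class AlreadyDuplicated(DedoubleError):
    """A breakpoint-duplication may only duplicate a family that is still single-copy."""


class ScenarioInvalidAtStep(DedoubleError):
    """A scenario step could not be applied; carries the failing step index."""

    def __init__(self, step: int, cause: Exception):
        super().__init__(f"scenario invalid at step {step}: {cause}")
        self.step = step
        self.cause = cause


class NotTotallyDuplicated(DedoubleError):
    """Operation requires a totally duplicated genome (every family present twice)."""


class NotUnichromosomal(DedoubleError):
    """Operation requires a genome consisting of a single linear chromosome."""


class UnorientedVertex(DedoubleError):
    """The overlap-graph vertex is unoriented (or already sorted)."""


class UnorientedGenomeError(DedoubleError):
    """Reversal dedoubling is only defined here for oriented genomes."""


class SizeLimitExceeded(DedoubleError):
    """Instance larger than the configured limit of an exact/brute-force routine."""


class ExhaustedResampling(DedoubleError):
    """The constrained simulator failed to draw an admissible instance."""


class InternalError(DedoubleError):
    """A constructive guarantee was violated; indicates a bug, not bad input."""
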