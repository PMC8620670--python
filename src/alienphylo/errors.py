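"""Exception hierarchy shared across the package."""


class AlienPhyloError(Exception):
    """Base class for all package-specific errors."""


class ChecklistError(AlienPhyloError):
    """Invalid checklist input (missing columns, bad tokens, duplicates)."""


class TreeError(AlienPhyloError):
    """Invalid phylogeny input (malformed Newick, missing branch lengths)."""


class AssemblageError(AlienPhyloError):
    """An assemblage violates a precondition (too small, taxa off-tree)."""


class NullModelError(AlienPhyloError):
    """Null-model construction failed (richness exceeds pool, etc.)."""


class OrdinationError(AlienPhyloError):
    """Invalid distance matrix handed to the ordination."""


class PipelineError(AlienPhyloError):
    """Stage-tagged failure raised by the orchestration layer."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
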