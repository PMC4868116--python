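"""Exception hierarchy shared across treekit modules."""


class TreekitError(Exception):
    """Base class for every error raised by treekit."""


class NewickError(TreekitError):
    """Malformed newick input; carries the character offset of the problem."""

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (at character {offset})"
        super().__init__(message)
        self.offset = offset


class TreeError(TreekitError):
    """Invalid tree operation (unknown labels, bad arguments, duplicates)."""


class ComparisonError(TreekitError):
    """A tree pair cannot be compared (e.g. fewer than 3 shared leaves)."""


class DecompositionError(TreekitError):
    """Duplication-aware decomposition failed or would explode."""


class TaxonomyError(TreekitError):
    """Taxonomy database build or query failure."""


class LRTError(TreekitError):
    """Likelihood-ratio test on a non-nested or unknown model pair."""


class ModelTSVError(TreekitError):
    """Malformed model-fit interchange file; carries a line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class AlignmentError(TreekitError):
    """Invalid alignment content or incompatible alignments."""
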