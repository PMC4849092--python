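"""Exception hierarchy shared across the package."""


class CorblosumError(Exception):
    """Base class for all errors raised by this package."""


class BlocksFormatError(CorblosumError):
    """A BLOCKS record is structurally invalid (e.g. segment/width mismatch)."""


class MatrixFormatError(CorblosumError):
    """Substitution-matrix text is malformed, asymmetric, or uses unknown labels."""


class EmptyCountsError(CorblosumError):
    """No cross-cluster pair was counted; no frequencies can be formed."""


class ZeroFrequencyError(CorblosumError):
    """Some residue pair was never observed and no pseudocount was requested."""

    def __init__(self, missing_pairs):
        self.missing_pairs = list(missing_pairs)
        pairs = ", ".join(f"{a}-{b}" for a, b in self.missing_pairs)
        super().__init__(
            f"{len(self.missing_pairs)} residue pair(s) with zero observed "
            f"frequency: {pairs}. Enable a pseudocount to score such inputs."
        )


class SearchResultFormatError(CorblosumError):
    """A tabular search-result line cannot be parsed."""


class AnnotationError(CorblosumError):
    """A relation references a domain without a superfamily annotation."""
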