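"""Exception hierarchy shared by all catmap modules."""


class CatmapError(Exception):
    """Base class for all catmap errors."""


class InvalidConfigError(CatmapError, ValueError):
    """A configuration value violates a precondition."""


class DataError(CatmapError, ValueError):
    """Input data violate a structural requirement."""


class FlankTruncationError(DataError):
    """A SNP sits too close to a scaffold edge for a full 71-mer flank."""


class ShortfallError(DataError):
    """Not enough eligible sites to satisfy a selection request."""


class UndefinedPairError(DataError):
    """A pairwise statistic is undefined (no overlapping information)."""
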