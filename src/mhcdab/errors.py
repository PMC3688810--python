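"""Exception hierarchy shared across the package."""


class MhcDabError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MhcDabError):
    """A parameter combination that cannot be honoured (bad weights, missing lineage...)."""


class FrameError(ConfigurationError):
    """A coding-sequence length that is not a whole number of codons."""


class GenerationError(MhcDabError):
    """Synthetic data could not be generated within the retry budget."""


class LayoutError(MhcDabError):
    """A specimen without a tag pair, or an inconsistent plate layout."""


class CapacityError(LayoutError):
    """More specimens than forward x reverse tag combinations."""


class SelectionError(MhcDabError):
    """Tag-set selection could not reach the requested size.

    Carries the best set found so the caller can inspect it.
    """

    def __init__(self, message, best_set=None):
        super().__init__(message)
        self.best_set = best_set or []


class SaturationError(MhcDabError):
    """A pairwise proportion of differences >= 3/4, outside the Jukes-Cantor domain."""


class DataError(MhcDabError):
    """Malformed or degenerate input data (empty bins, monomorphic matrices...)."""


class NamingError(MhcDabError):
    """An allele that cannot be named (empty species-occurrence set)."""


class DependencyError(MhcDabError):
    """A pipeline stage whose upstream outputs are missing."""


class ConvergenceError(MhcDabError):
    """Optimiser failure; carries the best point found."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best
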