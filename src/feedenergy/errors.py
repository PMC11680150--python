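"""Exception hierarchy shared across the pipeline."""


class FeedEnergyError(Exception):
    """Base class for all feedenergy errors."""


class InvalidProfileError(FeedEnergyError):
    """A nutrient profile violates its invariants (e.g. dm_pct <= 0)."""


class BasisMismatchError(FeedEnergyError):
    """Two quantities expressed on different bases were combined.

    Cross-table operations never convert silently: the caller must bring
    everything onto one declared basis first.
    """


class UnknownIngredientError(FeedEnergyError):
    """A formulation references an ingredient absent from the panel."""


class InsufficientDataError(FeedEnergyError):
    """Too few observations for the requested statistic."""


class UndefinedStatisticError(FeedEnergyError):
    """The statistic is undefined for this input (e.g. CV of a zero-mean vector)."""


class InvalidRecordError(FeedEnergyError):
    """A balance record violates a hard invariant (negative mass, zero intake)."""


class DesignError(FeedEnergyError):
    """A trial or replacement design is internally inconsistent."""


class EstimabilityError(FeedEnergyError):
    """The design matrix does not allow the requested contrasts."""
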