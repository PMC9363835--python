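"""Exception and warning types shared across the pipeline."""


class YieldGapError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(YieldGapError):
    """A column map, config file or parameter set is unusable."""


class ValidationError(YieldGapError):
    """Input rows violate a physical or schema invariant."""


class UnfillableGapError(YieldGapError):
    """Calendar gaps remain after exhausting all donor series."""

    def __init__(self, dates):
        self.dates = list(dates)
        super().__init__(
            f"{len(self.dates)} date(s) missing and absent from every donor: "
            + ", ".join(str(d) for d in self.dates[:10])
            + ("..." if len(self.dates) > 10 else "")
        )


class NoInteriorOptimumError(YieldGapError):
    """Fitted log-quadratic frontier is convex; no interior rainfall optimum."""


class NoWaterResponseError(YieldGapError):
    """Boundary-line slope is not positive; yield shows no water response."""


class MissingDataWarning(UserWarning):
    """More than the tolerated share of a weather series was gap-filled."""


class NegativeGapWarning(UserWarning):
    """Current yield exceeds an estimated ceiling (negative yield gap)."""


class NegativeInterceptWarning(UserWarning):
    """Boundary line crosses above the origin; water loss clamped to zero."""
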