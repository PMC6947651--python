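"""Error types raised across the package."""


class ParameterError(ValueError):
    """A configuration parameter is out of its valid range."""


class DataError(ValueError):
    """Input data violates an invariant (NaN, duplicate ids, shape mismatch)."""


class DegenerateWeightsError(ValueError):
    """Feature-sampling weights are all zero (or otherwise unusable)."""


class DegenerateNullError(ValueError):
    """An empirical null distribution has zero spread; no t-statistic exists."""
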