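"""Exception hierarchy shared by all thermonorms modules."""


class ThermonormsError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(ThermonormsError):
    """A table is missing a mandatory column or has an unusable dtype."""


class ValidationError(ThermonormsError):
    """A table or curve violates a dataset invariant."""


class NoGrowthError(ValidationError):
    """An operation that requires a nonzero growth signal received none."""
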