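"""Exception hierarchy."""


class SeamtrialError(Exception):
    """Base class for all package errors."""


class ValidationError(SeamtrialError, ValueError):
    """Invalid input data or parameter values."""


class IdentifiabilityError(ValidationError):
    """Too few uncensored records to identify the regression."""


class DegenerateSlopeError(ValidationError):
    """Slope too close to zero for the surrogate inversion X=(log T - a)/b."""


class ConfigurationError(SeamtrialError, ValueError):
    """A design / run configuration violates its invariants.

    ``fields`` lists every offending key so a user can fix a config file in
    one pass.
    """

    def __init__(self, fields):
        if isinstance(fields, str):
            fields = [fields]
        self.fields = list(fields)
        super().__init__("; ".join(self.fields))


class MonotoneInformationError(SeamtrialError, ValueError):
    """Final log-rank variance smaller than the interim variance."""


class SearchError(SeamtrialError, RuntimeError):
    """A sample-size search could not reach the target on the given grid."""
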