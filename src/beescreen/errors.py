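"""Named exceptions raised across the assessment pipeline."""


class BeescreenError(Exception):
    """Base class for all package errors."""


class UnknownUnitError(BeescreenError):
    """An application-rate unit is not one of the supported units."""


class ModeMismatchError(BeescreenError):
    """An operation was called on a scenario in the wrong exposure mode."""


class MissingEndpointError(BeescreenError):
    """A toxicity endpoint required for a risk-quotient route is absent."""

    def __init__(self, route: str):
        self.route = route
        super().__init__(f"missing toxicity endpoint for route: {route}")


class EmptyGroupError(BeescreenError):
    """A residue matrix group or record set contained no usable samples."""


class UnknownRuleError(BeescreenError):
    """An unrecognised censoring-substitution rule was requested."""


class InsufficientDataError(BeescreenError):
    """Too few observations to compute the requested statistic."""
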