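"""Exception hierarchy for mixdes.

All package-specific failures derive from :class:`MixdesError` so callers can
catch one type at the CLI boundary and map it to an exit code.
"""


class MixdesError(Exception):
    """Base class for all mixdes errors."""


class BoundViolationError(MixdesError, ValueError):
    """A blend lies outside the component bounds of its mixture region."""


class DegenerateRegionError(MixdesError, ValueError):
    """The mixture region has zero volume (lower bounds exhaust the total)."""


class RankDeficiencyError(MixdesError, ValueError):
    """A model matrix is rank deficient; the requested fit/design is not estimable."""


class InfeasibleDesignError(MixdesError, ValueError):
    """The requested run budget cannot support the requested model."""


class SchemaError(MixdesError, ValueError):
    """An input file does not conform to the expected tabular schema."""
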