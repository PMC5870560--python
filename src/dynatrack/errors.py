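"""Exception hierarchy.

All user-facing failures derive from :class:`DynatrackError` so the CLI can
catch one type and print a single-line diagnostic.
"""


class DynatrackError(Exception):
    """Base class for all dynatrack errors."""


class ConfigSyntaxError(DynatrackError):
    """The configuration text does not parse (malformed JSON)."""


class ConfigSemanticsError(DynatrackError):
    """The configuration parses but violates a registry invariant.

    The message always names the offending entity (track id, group id, ...).
    """


class RegionSyntaxError(DynatrackError):
    """A region string does not match ``chrom:start-end`` / ``chrom:start..end``."""


class FeatureFormatError(DynatrackError):
    """A feature file row is malformed; the message cites the line number."""


class ContractViolationError(DynatrackError):
    """An operation was called outside its stated precondition."""


class NavigationScriptError(DynatrackError):
    """A navigation script is malformed or a step is invalid for the state."""
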