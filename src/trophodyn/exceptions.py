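"""Exception hierarchy for trophodyn.

All trophodyn errors derive from :class:`TrophodynError` so callers can catch
the whole family; the concrete classes distinguish malformed files from
semantically invalid data and bad call arguments.
"""


class TrophodynError(Exception):
    """Base class for all trophodyn errors."""


class FormatError(TrophodynError):
    """A file does not have the documented structure (missing columns,
    unknown sector labels, unparsable fields)."""


class ValidationError(TrophodynError):
    """Structurally well-formed data violates a domain invariant
    (duplicate keys, trophic level out of range, negative catch)."""


class ConfigError(TrophodynError):
    """An analysis or simulation configuration is inconsistent
    (baseline year absent, class proportions not summing to one)."""


class InsufficientDataError(TrophodynError):
    """Too few observations for the requested computation
    (trend fits need at least three year/value pairs)."""
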