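"""Exception hierarchy for morphomap.

``MorphomapError`` is the base of every error the library raises on bad
input; internal bugs surface as ordinary Python exceptions.
"""


class MorphomapError(Exception):
    """Base class for all user-facing morphomap errors."""


class FeatureNameError(MorphomapError):
    """A feature name does not follow the CellProfiler naming convention."""


class SchemaError(MorphomapError):
    """A table is missing required columns or contains invalid values."""


class LayoutError(MorphomapError):
    """A plate layout request cannot be satisfied."""


class DegenerateInputError(MorphomapError):
    """An operation received input on which its statistic is undefined."""
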