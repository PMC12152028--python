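"""Exception hierarchy for stochreg."""


class StochregError(Exception):
    """Base class for all stochreg errors."""


class FormatError(StochregError):
    """Malformed input file (missing column, no header, too few rows)."""


class GridError(StochregError):
    """Time grid is not uniform to within tolerance, or not increasing."""


class DataError(StochregError):
    """Non-finite or otherwise unusable sample values."""


class DegenerateWindowError(StochregError):
    """A kernel window received zero total weight (empty support)."""
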