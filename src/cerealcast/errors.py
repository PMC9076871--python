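"""Exception types shared across the pipeline stages."""


class CerealcastError(Exception):
    """Base class for all package-specific errors."""


class CoverageError(CerealcastError):
    """Required (region, variable, year, month) cells are missing from an input."""


class DegenerateInputError(CerealcastError):
    """An input is constant or otherwise leaves a statistic undefined (SD = 0)."""


class CalendarError(CerealcastError):
    """A daily record does not cover a calendar month completely."""
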