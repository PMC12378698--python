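"""Exception hierarchy.

``CognavError`` is the base for everything the library raises on bad input
or bad configuration, so callers (and the CLI) can distinguish data problems
from programming errors.
"""


class CognavError(Exception):
    """Base class for all cognav errors."""


class ConfigurationError(CognavError):
    """Invalid configuration: too few layers, empty lexicon, bad options."""


class DataError(CognavError):
    """Invalid data content (malformed files, inconsistent tables)."""


class EdgeListParseError(DataError):
    """A malformed row in a delimited edge-list file.

    Carries the 1-based line number of the offending row.
    """

    def __init__(self, path, line_number: int, message: str):
        self.path = path
        self.line_number = line_number
        super().__init__(f"{path}:{line_number}: {message}")
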