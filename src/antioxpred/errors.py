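"""Exception hierarchy shared across the pipeline.

``InputError`` subclasses map to CLI exit code 2, ``NumericalError`` to 3.
"""


class InputError(ValueError):
    """Invalid user input: bad files, inconsistent records, bad config."""


class FormatError(InputError):
    """A file does not conform to its expected dialect."""


class ConsistencyError(InputError):
    """Two inputs that must describe the same object disagree."""


class NumericalError(RuntimeError):
    """A computation produced non-finite values or diverged."""
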