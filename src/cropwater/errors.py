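"""Exception hierarchy.

``InputError`` flags a bad argument value (a precondition violation);
``DataError`` flags malformed or inconsistent table content discovered while
reading or combining datasets. The CLI maps both to exit code 2, anything
else to 1.
"""


class CropwaterError(Exception):
    """Base class for all package-specific errors."""


class InputError(CropwaterError, ValueError):
    """An argument violates a documented precondition."""


class DataError(CropwaterError, ValueError):
    """A table is malformed, incomplete, or internally inconsistent."""
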