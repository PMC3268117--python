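"""Exception hierarchy shared across the package.

All errors derive from :class:`XenosigError` so callers can catch the
package's failures with a single except clause; each subclass also derives
from the closest built-in (ValueError/KeyError/OSError) so untargeted code
behaves sensibly.
"""


class XenosigError(Exception):
    """Base class for all xenosig errors."""


class FormatError(XenosigError, ValueError):
    """A file does not conform to the expected tab-delimited layout."""


class ResourceError(XenosigError, ValueError):
    """A packaged resource is missing or corrupted."""


class GeneLookupError(XenosigError, KeyError):
    """A requested gene symbol is absent from a matrix or list."""


class DegenerateInputError(XenosigError, ValueError):
    """Input is constant/empty in a way that makes the statistic undefined
    (constant proxy row, zero-scatter gene with s0 = 0, all-equal partition)."""


class AlignmentError(XenosigError, ValueError):
    """Sample identifiers do not line up between paired objects."""
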