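"""Exception hierarchy.

The CLI maps :class:`InputError` (and subclasses) to exit code 2 and
:class:`NumericError` to exit code 3.
"""


class OcclusalError(Exception):
    """Base class for all package errors."""


class InputError(OcclusalError):
    """Invalid or inconsistent user input (bad table, mismatched tooth, ...)."""


class DomainError(InputError):
    """A parameter outside its mathematical domain (e.g. lambda not in [0, 1])."""


class FormatError(InputError):
    """A file that does not parse (Newick, PLY/OBJ, CSV schema)."""


class TaxonLookupError(InputError):
    """A species name absent from the tree (after alias resolution)."""


class DegenerateInputError(InputError):
    """Input that makes the requested statistic undefined (constant trait, ...)."""


class NumericError(OcclusalError):
    """A numerical failure (singular covariance, non-finite likelihood)."""
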