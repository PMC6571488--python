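"""Exception types shared across the package."""


class BsaQtlError(Exception):
    """Base class for all package-specific errors."""


class MapFormatError(BsaQtlError, ValueError):
    """A tabular input file violates the expected dialect (parse-level)."""


class ValidationError(BsaQtlError, ValueError):
    """A parsed object violates a semantic invariant."""


class DegenerateNullError(BsaQtlError, ValueError):
    """The null model cannot be fit (e.g. all G' values identical).

    Usually indicates a constant or near-constant scan; check that the
    input counts vary across markers.
    """
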