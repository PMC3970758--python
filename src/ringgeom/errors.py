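"""Exception hierarchy.

Every error raised by this package derives from :class:`RingGeomError`
so callers (and the CLI) can catch one type.
"""


class RingGeomError(Exception):
    """Base class for all ringgeom errors."""


class StructureParseError(RingGeomError):
    """A coordinate file could not be read or violates an invariant."""


class SelectionError(RingGeomError):
    """An atom/residue selection resolved to nothing usable."""


class AtomLookupError(RingGeomError):
    """A specific chain/residue/atom requested by name is absent."""


class DegenerateGeometryError(RingGeomError):
    """Point configuration is too ill-conditioned for the requested fit."""


class FitError(RingGeomError):
    """A nonlinear fit could not be carried out on the given data."""


class ConfigError(RingGeomError):
    """A run configuration is malformed."""
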