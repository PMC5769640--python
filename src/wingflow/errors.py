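"""Exception types shared across wingflow modules."""


class WingflowError(Exception):
    """Base class for all wingflow errors."""


class InvalidParameterError(WingflowError, ValueError):
    """A numeric parameter violates its precondition."""


class GeometryError(WingflowError, ValueError):
    """A generated or loaded profile is geometrically inadmissible."""


class PlacementError(WingflowError, ValueError):
    """A profile placed outside the grid/domain it must fit in."""


class ProfileParseError(WingflowError, ValueError):
    """A profile text file could not be parsed or validated."""


class ConfigError(WingflowError, ValueError):
    """A case/study configuration file is invalid."""


class SolverError(WingflowError, RuntimeError):
    """The flow solver failed to converge or produced non-finite fields."""
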