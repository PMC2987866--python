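"""Exception hierarchy shared across modules."""


class WingmorphError(Exception):
    """Base class for all package-specific errors."""


class ParseError(WingmorphError):
    """A landmark file could not be parsed; message names record/line."""


class DatasetConsistencyError(WingmorphError):
    """Configurations within one dataset violate a dataset invariant."""


class ShapeMismatchError(WingmorphError):
    """Two configurations/datasets do not share the same landmark count."""


class DegenerateConfigurationError(WingmorphError):
    """A configuration has zero centroid size (all landmarks coincide)."""


class SingularGeometryError(WingmorphError):
    """Reference landmarks are collinear: the thin-plate spline system is singular."""


class RankError(WingmorphError):
    """A requested dimensionality exceeds what the data can support."""


class SingularityError(WingmorphError):
    """Pooled within-group covariance is singular and no ridge was requested."""


class ConsensusMismatchError(WingmorphError):
    """Shape variables computed against different consensuses were mixed."""
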