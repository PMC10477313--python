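"""Exception hierarchy.

All errors derive from :class:`SticklesimError` so callers can catch the
package's failures with one clause; most also derive from ``ValueError``
because they signal invalid inputs.
"""


class SticklesimError(Exception):
    """Base class for all package errors."""


class ParameterError(SticklesimError, ValueError):
    """A parameter lies outside its mathematical domain (e.g. 2*beta > kappa)."""


class InputError(SticklesimError, ValueError):
    """Malformed or out-of-range data passed to an operation."""


class DegenerateDataError(SticklesimError, ValueError):
    """Data carry no usable signal (all-identical samples, constant series)."""


class QualityError(SticklesimError, ValueError):
    """Data fail a quality gate (e.g. too large a fraction of missing frames)."""


class SimulationError(SticklesimError, RuntimeError):
    """The simulator could not advance (boundary redraw cap exceeded)."""


class GeometryError(SticklesimError, ValueError):
    """Impossible camera/ray geometry (parallel ray, total internal reflection)."""


class LocalizationError(SticklesimError, RuntimeError):
    """The depth solve for a tag observation has no admissible root."""


class FitError(SticklesimError, RuntimeError):
    """A model fit failed to converge or is underdetermined."""
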