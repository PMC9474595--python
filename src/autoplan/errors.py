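"""Package-wide exception types."""

__all__ = ["AutoplanError", "LandmarkError", "PlanGeometryError", "ConfigError"]


class AutoplanError(Exception):
    """Base class for planning failures."""


class LandmarkError(AutoplanError):
    """A bony landmark needed for aperture design is missing or undetectable.

    Raised, never silently ignored: an aperture built from a wrong landmark
    (e.g. a missing L4 contour shifting the superior border) produces an
    unusable plan.
    """


class PlanGeometryError(AutoplanError):
    """Beam/target geometry is inconsistent (empty intersection, empty PTV...)."""


class ConfigError(AutoplanError):
    """A configuration value is missing, malformed, or out of its accepted range."""
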