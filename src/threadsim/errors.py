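"""Exception hierarchy for threadsim."""


class ThreadSimError(Exception):
    """Base class for all threadsim errors."""


class InvalidTopologyError(ThreadSimError):
    """Rod topology is unusable (e.g. fewer than two centerline points)."""


class DegenerateGeometryError(ThreadSimError):
    """Geometry has collapsed (zero-length segment, coincident particles, ...)."""


class DiscretizationError(ThreadSimError):
    """Centerline segments violate the uniform-length discretization assumption."""


class InvalidOrientationError(ThreadSimError):
    """A quaternion that must be unit norm is not."""


class SingularSystemError(ThreadSimError):
    """A linear system required by a direct solve is numerically singular."""


class SchemaError(ThreadSimError):
    """A scene configuration file violates the documented schema."""
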