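"""Exception hierarchy for vrank-cascade.

All errors raised by the package derive from :class:`VRankCascadeError` so
callers can catch everything from this library with one clause.
"""


class VRankCascadeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(VRankCascadeError):
    """A scenario/config field is missing, out of range, or inconsistent."""


class ScenarioError(VRankCascadeError):
    """A structurally valid config describes an unusable scenario
    (e.g. an epicenter with no food-producing nodes, so the shock would
    be a no-op)."""


class DomainError(VRankCascadeError):
    """An economic primitive was called with out-of-domain values
    (negative quantities, zero marketed goods, ...)."""


class EmptiedNodeError(DomainError):
    """An operation that needs workers was applied to a depopulated node."""


class IsolatedNodeError(VRankCascadeError):
    """A neighborhood operation was applied to a node with no links."""


class PairingError(VRankCascadeError):
    """Two trajectories that must share a network/seed do not."""


class ConsistencyError(VRankCascadeError):
    """Internal invariant violated (bug trap): e.g. a flow exceeding the
    source stock, or a NaN/negative stock during a run."""
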