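"""Exception hierarchy for the mcs package."""


class MCSError(Exception):
    """Base class for all mcs-specific errors."""


class InvalidInputError(MCSError, ValueError):
    """Malformed or non-finite input data."""


class InvalidPairError(MCSError, ValueError):
    """A cluster pair (a, b) with a == b or labels not in the label order."""


class InvalidConfigError(MCSError, ValueError):
    """An inconsistent permutation or generator configuration."""


class DegenerateClusterError(MCSError, ValueError):
    """A cluster with fewer than two members; the mean intra-cluster
    distance needs at least one within-cluster pair."""


class EmptySegmentError(MCSError, ValueError):
    """Onset exclusion would remove an entire recording segment."""


class DegenerateWindowError(MCSError, ValueError):
    """A state vector with zero across-channel variance cannot be z-scored."""


class ScheduleError(MCSError, ValueError):
    """Overlapping or out-of-range condition-schedule intervals."""
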