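"""Exception and warning types shared across the package."""


class WireconError(Exception):
    """Base class for all wirecon errors."""


class InvalidSpecError(WireconError, ValueError):
    """A generator or grid specification violates its invariants."""


class InvalidInputError(WireconError, ValueError):
    """An input object (graph, stack, table) violates a precondition."""


class InvalidRuleError(WireconError, ValueError):
    """Unknown generative wiring rule name."""


class InfeasibleTargetError(WireconError, ValueError):
    """Requested edge count cannot be reached from the given seed."""


class SaturatedGraphError(WireconError, RuntimeError):
    """No unconnected node pairs remain to wire."""


class MissingTraceError(WireconError, ValueError):
    """A simulation trace lacks the per-iteration records required."""


class DegenerateResponseError(WireconError, ValueError):
    """A response vector has zero variance and cannot be decomposed."""


class DegenerateSignalWarning(UserWarning):
    """A planted association cannot be expressed (e.g. zero-variance truth)."""
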