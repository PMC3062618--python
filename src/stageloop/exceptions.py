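"""Exception types raised across the package."""


class StageloopError(Exception):
    """Base class for all package-specific errors."""


class DesignError(StageloopError):
    """An experimental design is structurally invalid (e.g. a loop with < 2 stages)."""


class LayoutError(StageloopError):
    """Spot grid capacity is too small for the requested genes + controls."""


class InsufficientControlsError(StageloopError):
    """Fewer than two control spots: no threshold SD can be computed."""


class DesignDeficientError(StageloopError):
    """Too few arrays/channels to fit the requested model."""


class ReconciliationError(StageloopError):
    """Design file and spot tables disagree about which arrays exist."""
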