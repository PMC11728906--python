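"""Exception hierarchy shared across the toolkit."""


class OctCoregError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(OctCoregError, ValueError):
    """An object or parameter violates a declared invariant."""


class FormatError(OctCoregError, ValueError):
    """On-disk data does not match the expected layout."""


class MetadataError(FormatError):
    """Required sidecar metadata is missing or inconsistent."""


class NoSurfaceError(OctCoregError):
    """No tissue surface could be detected anywhere in a volume."""


class InsufficientDataError(OctCoregError):
    """Too little valid data to run an operation (e.g. mostly no-data plane)."""


class PlanningError(OctCoregError, ValueError):
    """A tile plan cannot satisfy the coverage/overlap constraints."""


class StageError(OctCoregError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
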