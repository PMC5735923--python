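"""Exception hierarchy for the blastoquant pipeline."""


class BlastoquantError(Exception):
    """Base class for all pipeline errors."""


class InputError(BlastoquantError):
    """Missing file, unreadable input, or invalid argument."""


class FormatError(InputError):
    """Image exists but cannot be decoded or has an unsupported pixel format."""


class DetectionError(BlastoquantError):
    """The embryo circle could not be found in either radius range.

    Carries the per-stage accumulator diagnostics so failures can be
    inspected (``stage_diagnostics`` is a list of dicts, one per stage).
    """

    def __init__(self, message, stage_diagnostics=None):
        super().__init__(message)
        self.stage_diagnostics = stage_diagnostics or []


class EmptyRegionError(BlastoquantError):
    """A statistic was requested on a region with no masked pixels."""


class DegenerateRegionError(BlastoquantError):
    """Region geometry is degenerate (e.g. reduced radius < 1 px)."""


class PhantomSpecError(BlastoquantError):
    """A synthetic-phantom specification violates its invariants."""


class ExtractionError(BlastoquantError):
    """Full-pipeline failure on one image; records the stage that failed."""

    def __init__(self, image_id, stage, cause):
        super().__init__(f"extraction failed for {image_id!r} at stage {stage!r}: {cause}")
        self.image_id = image_id
        self.stage = stage
        self.cause = cause


class TableError(BlastoquantError):
    """Malformed feature/grade table."""
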