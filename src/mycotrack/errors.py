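"""Exception hierarchy for mycotrack."""


class MycotrackError(Exception):
    """Base class for all package-specific errors."""


class DimensionMismatchError(MycotrackError):
    """Images in one sequence do not share a single height x width."""


class FrameMetadataError(MycotrackError):
    """Invalid frame index or non-increasing acquisition times."""


class ParameterError(MycotrackError):
    """An operation parameter is out of its valid range."""


class DegenerateHistogramError(MycotrackError):
    """Automatic thresholding attempted on a single-valued image."""


class CellLostError(MycotrackError):
    """Propagation could not place the cell in the current frame."""

    def __init__(self, cell: str | None = None, frame: int | None = None,
                 reason: str = ""):
        self.cell = cell
        self.frame = frame
        self.reason = reason
        where = f"cell {cell!r}" if cell else "cell"
        at = f" at frame {frame}" if frame is not None else ""
        super().__init__(f"{where} lost{at}: {reason}")


class LineageError(MycotrackError):
    """Naming-scheme or cell-lifetime contract violated."""


class NotDefinedError(MycotrackError):
    """A derived quantity is undefined for this cell (e.g. censored)."""


class DatastoreError(MycotrackError):
    """Schema, integrity or lookup failure in the project database."""


class MeasurementError(MycotrackError):
    """ROI measurement failed (e.g. mask empty after erosion)."""
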