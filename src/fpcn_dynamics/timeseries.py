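"""Shared ROI time-series container used across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RoiTimeSeries:
    """A time x ROI signal matrix with its repetition time.

    ``data`` holds one column per ROI in ``roi_labels`` order; ``meta`` carries
    provenance (seed, subject/run identifiers, planted truth tags).
    """

    data: np.ndarray
    roi_labels: tuple[str, ...]
    repetition_time: float
    subject: "int | str | None" = None
    run: "int | str | None" = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (time x ROI)")
        if self.data.shape[1] != len(self.roi_labels):
            raise ValueError(
                f"data has {self.data.shape[1]} columns but "
                f"{len(self.roi_labels)} roi_labels were given"
            )
        self.roi_labels = tuple(self.roi_labels)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.repetition_time

    def column(self, roi: str) -> np.ndarray:
        """Return one ROI's series by label."""
        try:
            j = self.roi_labels.index(roi)
        except ValueError:
            raise KeyError(f"unknown ROI {roi!r}; have {self.roi_labels}") from None
        return self.data[:, j]

    def copy(self) -> "RoiTimeSeries":
        return RoiTimeSeries(
            self.data.copy(), self.roi_labels, self.repetition_time,
            self.subject, self.run, dict(self.meta),
        )
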