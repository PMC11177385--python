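"""Core in-memory containers for subject time-series and per-site datasets."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RoiTimeSeries:
    """One subject's ROI time-series.

    Attributes
    ----------
    subject_id : str
        Unique subject identifier.
    task_index : int
        Index of the site/task this subject belongs to.
    matrix : numpy.ndarray
        T x N real matrix; rows are acquisition time nodes, columns are
        atlas brain regions. Must be free of NaN/Inf.
    label : int
        Diagnostic label: 1 = illness (e.g. ASD), 0 = no disease (control).
    harmonized : bool
        True if the series was truncated or padded to a target length.
    """

    subject_id: str
    task_index: int
    matrix: np.ndarray
    label: int
    harmonized: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError(
                f"matrix for subject {self.subject_id!r} must be 2-D, "
                f"got shape {self.matrix.shape}"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError(
                f"matrix for subject {self.subject_id!r} contains non-finite entries"
            )
        if self.label not in (0, 1):
            raise ValueError(
                f"label for subject {self.subject_id!r} must be 0 or 1, got {self.label}"
            )

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[1]


@dataclass
class TaskDataset:
    """All labelled samples of one task (one acquisition site).

    Attributes
    ----------
    task_index : int
        Task index d, shared by every sample.
    samples : list of RoiTimeSeries
    name : str
        Human-readable site name (e.g. "NYU").
    """

    task_index: int
    samples: list[RoiTimeSeries] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        for s in self.samples:
            if s.task_index != self.task_index:
                raise ValueError(
                    f"sample {s.subject_id!r} has task_index {s.task_index}, "
                    f"dataset has {self.task_index}"
                )

    def __len__(self) -> int:
        return len(self.samples)

    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=int)

    def stacked(self) -> np.ndarray:
        """Samples as one (n, T, N) array; raises if shapes are inconsistent."""
        shapes = {s.matrix.shape for s in self.samples}
        if len(shapes) > 1:
            raise ValueError(
                f"task {self.task_index} has inconsistent sample shapes {shapes}; "
                "harmonize lengths first"
            )
        return np.stack([s.matrix for s in self.samples])
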