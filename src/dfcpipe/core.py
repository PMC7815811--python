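"""Core containers: region time series and rigid-body motion traces.

The pipeline's central in-memory object is a regions x volumes matrix of
BOLD-like signal with a repetition time (TR) and ordered region labels.
Motion is carried as a per-volume table of six rigid-body parameters
(three translations in mm, three rotations in radians).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RegionTimeSeries", "MotionTrace"]

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


@dataclass
class RegionTimeSeries:
    """Per-subject regions x volumes signal matrix.

    Parameters
    ----------
    values : ndarray, shape (n_regions, n_volumes)
        Signal values in arbitrary BOLD units. Must be finite.
    tr : float
        Repetition time (sampling interval) in seconds.
    region_labels : list of str
        Ordered, unique region identifiers, one per row.
    subject_id : str
        Free-form subject identifier.
    """

    values: np.ndarray
    tr: float
    region_labels: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D regions x volumes matrix")
        if self.values.shape[1] < 1:
            raise ValueError("at least one volume is required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        self.region_labels = [str(lab) for lab in self.region_labels]
        if len(self.region_labels) != self.values.shape[0]:
            raise ValueError("one label per region row is required")
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValueError("region labels must be unique")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]

    @property
    def duration_seconds(self) -> float:
        return self.n_volumes * self.tr

    def copy_with(self, **kwargs) -> "RegionTimeSeries":
        return replace(self, **kwargs)

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV: one row per volume, one column per region label."""
        df = pd.DataFrame(self.values.T, columns=self.region_labels)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, tr: float, subject_id: str = ""
    ) -> "RegionTimeSeries":
        df = pd.read_csv(path, sep="\t")
        return cls(
            values=df.to_numpy().T,
            tr=tr,
            region_labels=list(df.columns),
            subject_id=subject_id,
        )


@dataclass
class MotionTrace:
    """Per-volume rigid-body realignment parameters.

    ``params`` has one row per volume and six columns: translations along
    x, y, z in millimetres, then rotations about x, y, z in radians.
    """

    params: np.ndarray
    subject_id: str = ""
    columns: tuple[str, ...] = field(default=MOTION_COLUMNS)

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion parameters must be a volumes x 6 matrix")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("motion parameters contain non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    @property
    def translations_mm(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations_rad(self) -> np.ndarray:
        return self.params[:, 3:]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.params, columns=list(self.columns)).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path, subject_id: str = "") -> "MotionTrace":
        df = pd.read_csv(path, sep="\t")
        return cls(params=df.to_numpy(), subject_id=subject_id)
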