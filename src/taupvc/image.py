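"""Core in-memory containers for dynamic PET data.

A :class:`DynamicImage` bundles a 4D activity array (x, y, z, frame) with
its frame timing and voxel geometry.  All activities are in Bq/mL; frame
timing is kept in seconds (matching the sidecar TSV convention) and exposed
in minutes where kinetic modelling needs it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError

__all__ = ["FrameSchedule", "DynamicImage"]


@dataclass(frozen=True)
class FrameSchedule:
    """Frame timing: start and duration of each frame, in seconds.

    Supports non-contiguous schedules (acquisition breaks): starts must be
    strictly increasing and frames must not overlap, but gaps are allowed.
    """

    start_s: np.ndarray
    duration_s: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start_s, dtype=float)
        dur = np.asarray(self.duration_s, dtype=float)
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "duration_s", dur)
        if start.ndim != 1 or start.shape != dur.shape:
            raise ConfigurationError("start_s and duration_s must be 1D and equal length")
        if len(start) == 0:
            raise ConfigurationError("frame schedule is empty")
        if np.any(dur <= 0):
            raise ConfigurationError("frame durations must be positive")
        if np.any(np.diff(start) <= 0):
            raise ConfigurationError("frame starts must be strictly increasing")
        if np.any(start[1:] < (start + dur)[:-1] - 1e-9):
            raise ConfigurationError("frames overlap")

    @property
    def n_frames(self) -> int:
        return len(self.start_s)

    @property
    def end_s(self) -> np.ndarray:
        return self.start_s + self.duration_s

    @property
    def mid_s(self) -> np.ndarray:
        return self.start_s + self.duration_s / 2.0

    @property
    def mid_min(self) -> np.ndarray:
        return self.mid_s / 60.0

    @property
    def duration_min(self) -> np.ndarray:
        return self.duration_s / 60.0

    def to_array(self) -> np.ndarray:
        return np.column_stack([self.start_s, self.duration_s])

    @classmethod
    def from_pairs(cls, pairs) -> "FrameSchedule":
        arr = np.asarray(pairs, dtype=float)
        return cls(arr[:, 0], arr[:, 1])


@dataclass
class DynamicImage:
    """4D dynamic PET volume with frame timing and voxel geometry."""

    voxel_data: np.ndarray  # (nx, ny, nz, n_frames), Bq/mL
    frames: FrameSchedule
    voxel_size: np.ndarray = field(default_factory=lambda: np.array([2.0, 2.0, 2.0]))
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxel_data = np.asarray(self.voxel_data)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if self.voxel_data.ndim != 4:
            raise ConfigurationError("voxel_data must be 4D (x, y, z, frame)")
        if self.voxel_data.shape[3] != self.frames.n_frames:
            raise ConfigurationError(
                f"frame count mismatch: data has {self.voxel_data.shape[3]} frames, "
                f"schedule has {self.frames.n_frames}"
            )
        if self.voxel_size.shape != (3,) or np.any(self.voxel_size <= 0):
            raise ConfigurationError("voxel_size must be three positive values (mm)")
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size, 1.0])

    @property
    def shape(self) -> tuple:
        return self.voxel_data.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.frames.n_frames

    def copy_with(self, voxel_data: np.ndarray) -> "DynamicImage":
        """New image sharing geometry/timing with replaced voxel data."""
        return DynamicImage(
            voxel_data=voxel_data,
            frames=self.frames,
            voxel_size=self.voxel_size.copy(),
            affine=None if self.affine is None else self.affine.copy(),
        )
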