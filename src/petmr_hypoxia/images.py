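"""In-memory image containers: multi-echo MRI series, SUV images, ROI masks.

Every container carries its :class:`~petmr_hypoxia.geometry.GridGeometry`;
operations that combine containers check grid compatibility and never
resample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .geometry import GridGeometry

#: ROI labels used throughout the study.
ROI_LABELS = (
    "GTV-T", "GTV-LN", "NT", "HSV-T", "HSV-LN", "nonHSV-T", "nonHSV-LN",
    "background", "hypoxic-truth",
)

Tracer = Literal["FMISO", "FDG"]
UnitsState = Literal["suv", "nt_normalized"]


@dataclass
class MultiEchoSeries:
    """4-D magnitude gradient-echo signal (space x echo) with its echo times.

    ``signal`` has shape ``geometry.shape + (len(echo_times),)``; echo times
    are in ms and strictly increasing.
    """

    signal: np.ndarray
    echo_times: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.echo_times.ndim != 1 or self.echo_times.size == 0:
            raise ValueError("echo_times must be a non-empty 1-D list (ms)")
        if np.any(self.echo_times <= 0) or np.any(np.diff(self.echo_times) <= 0):
            raise ValueError("echo_times must be strictly increasing and positive")
        expected = self.geometry.shape + (self.echo_times.size,)
        if self.signal.shape != expected:
            raise ValueError(
                f"signal shape {self.signal.shape} does not match grid+echoes {expected}")
        if not np.all(np.isfinite(self.signal)) or np.any(self.signal < 0):
            raise ValueError("signal must be finite and non-negative magnitude data")

    @property
    def n_echoes(self) -> int:
        return int(self.echo_times.size)


@dataclass
class SuvImage:
    """3-D tracer uptake in SUV units, or dimensionless after NT normalization."""

    values: np.ndarray
    tracer: Tracer
    geometry: GridGeometry
    units_state: UnitsState = "suv"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.geometry.shape}")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("SUV values must be finite and non-negative")
        if self.tracer not in ("FMISO", "FDG"):
            raise ValueError(f"unknown tracer {self.tracer!r}")
        if self.units_state not in ("suv", "nt_normalized"):
            raise ValueError(f"unknown units_state {self.units_state!r}")

    def with_values(self, values: np.ndarray, units_state: UnitsState | None = None) -> "SuvImage":
        return replace(self, values=values,
                       units_state=self.units_state if units_state is None else units_state)


@dataclass
class RoiMask:
    """Binary region-of-interest mask on the study grid."""

    mask: np.ndarray
    label: str
    geometry: GridGeometry
    week: int | None = None

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.dtype != bool:
            uniq = np.unique(mask)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be boolean / {0,1}")
            mask = mask.astype(bool)
        if mask.shape != self.geometry.shape:
            raise ValueError(
                f"mask shape {mask.shape} != grid shape {self.geometry.shape}")
        self.mask = mask

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.mask))

    @property
    def is_empty(self) -> bool:
        return self.n_voxels == 0

    def volume_ml(self) -> float:
        """Geometric volume: voxel count x voxel volume, in ml."""
        return self.n_voxels * self.geometry.voxel_volume_mm3 / 1000.0

    def relabel(self, label: str, week: int | None = None) -> "RoiMask":
        return RoiMask(mask=self.mask, label=label, geometry=self.geometry,
                       week=self.week if week is None else week)
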