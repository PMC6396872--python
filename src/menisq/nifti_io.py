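"""NIfTI input/output and the in-memory multi-echo series container.

The echo dimension is the 4th NIfTI axis and the echo-time schedule lives in
a plain JSON/YAML sidecar, never in NIfTI header timing fields (their
dialects vary between tools). Affines are passed through untouched; all
internal coordinates are 0-based voxel indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .decay_models import EchoSchedule

__all__ = [
    "EchoSeries",
    "read_echo_series",
    "write_echo_series",
    "read_volume",
    "read_label_map",
    "write_volume",
    "default_sidecar_path",
]


@dataclass
class EchoSeries:
    """A 4D magnitude volume (x, y, z, echo) with its echo schedule (ms)."""

    data: np.ndarray
    schedule: EchoSchedule
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("EchoSeries data must be 4D (x, y, z, echo)")
        if self.data.shape[3] != len(self.schedule):
            raise ValueError(
                f"series has {self.data.shape[3]} echoes but schedule lists "
                f"{len(self.schedule)}"
            )

    @property
    def spatial_shape(self):
        return self.data.shape[:3]

    @property
    def n_echoes(self) -> int:
        return self.data.shape[3]

    @property
    def first_echo(self) -> np.ndarray:
        return self.data[..., 0]


def default_sidecar_path(series_path) -> Path:
    """Sidecar path for a series: strip .nii/.nii.gz and append ``_te.json``."""
    name = Path(series_path).name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
            break
    return Path(series_path).parent / f"{name}_te.json"


def write_echo_series(series: EchoSeries, path, sidecar_path=None) -> Path:
    """Write the 4D volume plus the echo-time sidecar; returns the sidecar path."""
    path = Path(path)
    nib.save(nib.Nifti1Image(series.data, series.affine), str(path))
    sidecar = Path(sidecar_path) if sidecar_path else default_sidecar_path(path)
    series.schedule.to_file(sidecar)
    return sidecar


def read_echo_series(path, sidecar_path=None) -> EchoSeries:
    """Read a 4D NIfTI series and its echo-time sidecar.

    Raises if the echo counts disagree or the schedule is not strictly
    increasing; warns when every echo time is below 0.1, which almost always
    means the sidecar was written in seconds instead of milliseconds.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path} is {data.ndim}D; expected a 4D multi-echo series")
    sidecar = Path(sidecar_path) if sidecar_path else default_sidecar_path(path)
    schedule = EchoSchedule.from_file(sidecar)
    if len(schedule) != data.shape[3]:
        raise ValueError(
            f"sidecar lists {len(schedule)} echo times but {path} holds "
            f"{data.shape[3]} echo volumes"
        )
    if max(schedule.te_ms) < 0.1:
        warnings.warn(
            "all echo times are < 0.1; schedules are expected in milliseconds "
            "— were these written in seconds?",
            stacklevel=2,
        )
    return EchoSeries(data, schedule, affine=np.asarray(img.affine))


def write_volume(volume: np.ndarray, path, affine=None) -> None:
    """Write a single 3D map (float or integer) as NIfTI."""
    affine = np.eye(4) if affine is None else np.asarray(affine)
    vol = np.asarray(volume)
    if vol.dtype == bool:
        vol = vol.astype(np.uint8)
    nib.save(nib.Nifti1Image(vol, affine), str(path))


def read_volume(path):
    """Read a 3D NIfTI map; returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), np.asarray(img.affine)


def read_label_map(path):
    """Read an integer ROI label volume; returns (labels, affine)."""
    data, affine = read_volume(path)
    labels = np.rint(data).astype(int)
    if not np.allclose(data, labels):
        raise ValueError(f"{path} does not contain integer labels")
    return labels, affine
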