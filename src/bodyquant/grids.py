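"""Physical-unit-aware 3D volume containers.

Conventions used throughout the package:

* Axis order is ``(z, y, x)`` everywhere — arrays, spacings, coordinates.
* All physical coordinates and spacings are in micrometres (µm); volumes
  are reported in mm³ (1 mm³ = 1e9 µm³).
* Voxel indices are 0-based and a voxel's physical position is its
  **center**: ``index * spacing + spacing / 2 + origin``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AXES = ("z", "y", "x")

__all__ = [
    "AXES",
    "VolumeGrid",
    "LabelVolume",
    "GeometryMismatchError",
    "check_same_geometry",
    "axis_index",
]


class GeometryMismatchError(ValueError):
    """Two volumes that must share shape/spacing/origin do not."""


def axis_index(axis: str | int) -> int:
    """Map an axis name ('z'/'y'/'x') or integer to its array dimension."""
    if isinstance(axis, str):
        try:
            return AXES.index(axis.lower())
        except ValueError:
            raise ValueError(f"axis must be one of {AXES}, got {axis!r}") from None
    if axis not in (0, 1, 2):
        raise ValueError(f"axis index must be 0, 1 or 2, got {axis}")
    return int(axis)


def _validate_geometry(data: np.ndarray, spacing_um, origin_um) -> tuple[tuple, tuple]:
    if data.ndim != 3:
        raise ValueError(f"volume data must be 3D (z, y, x); got ndim={data.ndim}")
    spacing = tuple(float(s) for s in spacing_um)
    origin = tuple(float(o) for o in origin_um)
    if len(spacing) != 3 or len(origin) != 3:
        raise ValueError("spacing_um and origin_um must have one entry per axis (z, y, x)")
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"spacing_um must be positive and finite on every axis, got {spacing}")
    if any(not np.isfinite(o) for o in origin):
        raise ValueError(f"origin_um must be finite, got {origin}")
    return spacing, origin


@dataclass
class VolumeGrid:
    """A 3D scalar intensity field with per-axis physical voxel spacing.

    Parameters
    ----------
    data
        3D array, axis order (z, y, x), arbitrary intensity units.
    spacing_um
        Physical voxel size per axis in µm.
    origin_um
        Physical position (µm) of the *corner* of voxel (0, 0, 0); the
        voxel's center is at ``origin_um + spacing_um / 2``.
    """

    data: np.ndarray
    spacing_um: tuple[float, float, float]
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing_um, self.origin_um = _validate_geometry(
            self.data, self.spacing_um, self.origin_um
        )
        if self.data.size and not np.all(np.isfinite(self.data)):
            raise ValueError("intensity volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing_um))

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical size of the grid per axis (µm)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing_um))

    def voxel_centers_um(self, indices: np.ndarray) -> np.ndarray:
        """Physical center positions (µm) of integer voxel indices, shape (n, 3)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return (idx + 0.5) * np.asarray(self.spacing_um) + np.asarray(self.origin_um)

    def same_geometry_as(self, other: "VolumeGrid | LabelVolume") -> bool:
        return (
            self.shape == other.shape
            and self.spacing_um == other.spacing_um
            and self.origin_um == other.origin_um
        )


@dataclass
class LabelVolume:
    """A 3D non-negative integer field sharing VolumeGrid geometry.

    Label 0 is reserved for background. ``label_names`` optionally maps
    label values to human-readable names (e.g. organ regions).
    """

    data: np.ndarray
    spacing_um: tuple[float, float, float]
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label_names: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing_um, self.origin_um = _validate_geometry(
            self.data, self.spacing_um, self.origin_um
        )
        if not np.issubdtype(self.data.dtype, np.integer):
            if np.issubdtype(self.data.dtype, np.bool_):
                self.data = self.data.astype(np.uint8)
            else:
                rounded = np.round(self.data)
                if not np.array_equal(self.data, rounded):
                    raise ValueError(
                        "label volume must be integer-valued; found fractional values"
                    )
                self.data = rounded.astype(np.int64)
        if self.data.size and self.data.min() < 0:
            raise ValueError("label volume must be non-negative (0 = background)")
        if self.label_names is not None:
            self.label_names = {int(k): str(v) for k, v in self.label_names.items()}

    # shared geometry helpers (kept duplicated rather than inherited so the
    # two types stay simple frozen-ish dataclasses)
    shape = VolumeGrid.shape
    voxel_volume_um3 = VolumeGrid.voxel_volume_um3
    extent_um = VolumeGrid.extent_um
    voxel_centers_um = VolumeGrid.voxel_centers_um
    same_geometry_as = VolumeGrid.same_geometry_as

    def name_of(self, label: int) -> str:
        """Human-readable name for a label; 0 maps to 'none'."""
        if label == 0:
            return "none"
        if self.label_names and int(label) in self.label_names:
            return self.label_names[int(label)]
        return f"region_{int(label)}"

    def is_binary(self) -> bool:
        if self.data.size == 0:
            return True
        mx = int(self.data.max())
        return mx <= 1


def check_same_geometry(a: VolumeGrid | LabelVolume, b: VolumeGrid | LabelVolume) -> None:
    """Raise :class:`GeometryMismatchError` unless a and b share shape, spacing and origin."""
    if not a.same_geometry_as(b):
        raise GeometryMismatchError(
            f"geometry mismatch: shape {a.shape} vs {b.shape}, "
            f"spacing {a.spacing_um} vs {b.spacing_um}, "
            f"origin {a.origin_um} vs {b.origin_um}"
        )
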