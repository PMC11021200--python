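"""Thresholding, axial intensity profiles, penetration depth and group tests.

Penetration depth is defined as the contiguous above-threshold run of
slice-mean intensity from the designated entry surface — the physical
notion of a staining front advancing into tissue — not the total count
of above-threshold slices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage.filters import threshold_otsu

from .grids import LabelVolume, VolumeGrid, axis_index, check_same_geometry

logger = logging.getLogger(__name__)

__all__ = [
    "ProfileCurve",
    "GroupStats",
    "otsu_threshold",
    "threshold_mask",
    "axial_profile",
    "penetration_depth",
    "group_compare",
    "anova_compare",
]


@dataclass
class ProfileCurve:
    """Per-slice mean intensity vs depth from an entry surface.

    ``positions_um`` are voxel-center depths, strictly increasing;
    ``values`` holds one mean per slice (NaN where the ROI is empty on a
    slice).
    """

    axis: str
    positions_um: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions_um.shape != self.values.shape:
            raise ValueError("positions_um and values must have equal length")
        if len(self.positions_um) > 1 and not np.all(np.diff(self.positions_um) > 0):
            raise ValueError("positions_um must be strictly increasing")

    @property
    def slice_spacing_um(self) -> float:
        if len(self.positions_um) > 1:
            return float(self.positions_um[1] - self.positions_um[0])
        return float(2 * self.positions_um[0]) if len(self.positions_um) else 0.0


@dataclass
class GroupStats:
    """Two-sample comparison result, reported as mean ± s.d. per group."""

    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t: float
    p: float
    equal_var: bool = True

    def as_dict(self) -> dict:
        return {
            "n_a": self.n_a,
            "n_b": self.n_b,
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
            "sd_a": self.sd_a,
            "sd_b": self.sd_b,
            "t": self.t,
            "p": self.p,
            "equal_var": self.equal_var,
        }


def otsu_threshold(volume: VolumeGrid) -> float:
    """Otsu threshold on a 256-bin histogram of finite intensities."""
    vals = volume.data[np.isfinite(volume.data)]
    if vals.size == 0 or np.ptp(vals) == 0:
        raise ValueError(
            "Otsu threshold undefined on a constant volume; use method='fixed'"
        )
    return float(threshold_otsu(vals, nbins=256))


def threshold_mask(
    volume: VolumeGrid, method: str = "otsu", value: float | None = None
) -> LabelVolume:
    """Binarize an intensity volume: foreground where intensity >= threshold."""
    if volume.data.size == 0:
        raise ValueError("cannot threshold an empty volume")
    if method == "fixed":
        if value is None:
            raise ValueError("method='fixed' requires a threshold value")
        thr = float(value)
    elif method == "otsu":
        thr = otsu_threshold(volume)
    else:
        raise ValueError(f"method must be 'fixed' or 'otsu', got {method!r}")
    logger.info("threshold_mask: method=%s threshold=%g", method, thr)
    mask = (volume.data >= thr).astype(np.uint8)
    return LabelVolume(mask, volume.spacing_um, volume.origin_um)


def axial_profile(
    volume: VolumeGrid,
    axis: str | int = "z",
    entry: str = "low",
    roi: LabelVolume | None = None,
) -> ProfileCurve:
    """Mean intensity per slice along an axis, ordered from the entry surface.

    Depth of slice *i* (counting from the entry surface) is the voxel
    center depth ``(i + 0.5) * spacing``. With ``roi`` given, only ROI
    voxels contribute; a slice with an empty ROI gets NaN.
    """
    ax = axis_index(axis)
    if entry not in ("low", "high"):
        raise ValueError("entry must be 'low' or 'high'")
    if roi is not None:
        check_same_geometry(volume, roi)
        mask = roi.data.astype(bool)
        data = np.where(mask, volume.data, np.nan)
        other = tuple(i for i in range(3) if i != ax)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            means = np.nanmean(data, axis=other)
        counts = mask.sum(axis=other)
        means = np.where(counts > 0, means, np.nan)
    else:
        other = tuple(i for i in range(3) if i != ax)
        means = volume.data.mean(axis=other)

    if entry == "high":
        means = means[::-1]
    n = len(means)
    sp = volume.spacing_um[ax]
    positions = (np.arange(n) + 0.5) * sp
    return ProfileCurve(axis="zyx"[ax], positions_um=positions, values=np.asarray(means))


def penetration_depth(profile: ProfileCurve, threshold: float) -> float:
    """Depth (µm) of the contiguous above-threshold run from the surface.

    Returns the depth of the deepest slice such that *every* slice up to
    and including it has mean intensity >= threshold; 0 if the first
    slice is already below; the full axial extent if no slice is below.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if len(profile.values) == 0:
        raise ValueError("profile is empty")
    above = np.asarray(profile.values) >= threshold  # NaN compares False
    if not above[0]:
        return 0.0
    if above.all():
        return float(profile.positions_um[-1] + profile.slice_spacing_um / 2)
    k = int(np.argmin(above))  # first below-threshold slice
    return float(profile.positions_um[k - 1])


def _group_arr(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < 2:
        raise ValueError(f"group {name} needs n >= 2, got n = {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"group {name} contains non-finite values")
    return arr


def group_compare(values_a, values_b, equal_var: bool = True) -> GroupStats:
    """Two-sided unpaired two-sample t test.

    Pooled-variance (classical) by default; ``equal_var=False`` selects
    Welch's test. Two zero-variance groups with equal means give t = 0,
    p = 1 rather than NaN.
    """
    a = _group_arr(values_a, "a")
    b = _group_arr(values_b, "b")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return GroupStats(
            len(a), len(b), float(a.mean()), float(b.mean()),
            0.0, 0.0, 0.0, 1.0, equal_var,
        )
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupStats(
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        t=float(t),
        p=float(p),
        equal_var=equal_var,
    )


def anova_compare(*groups) -> tuple[float, float]:
    """One-way ANOVA across >= 2 groups; returns (F, p)."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrs = [_group_arr(g, str(i)) for i, g in enumerate(groups)]
    f, p = stats.f_oneway(*arrs)
    return float(f), float(p)
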