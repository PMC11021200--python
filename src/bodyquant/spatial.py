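"""Nearest-neighbor distances, region densities and colocalization.

All distances are centroid-to-centroid Euclidean distances in physical
µm. Missing distances (no eligible neighbor) are NaN and are excluded
from summaries with the exclusion count reported, never imputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from scipy import stats

from .grids import LabelVolume, check_same_geometry

__all__ = [
    "NN_TABLE_COLUMNS",
    "nn_distances",
    "volume_distance_join",
    "volume_distance_summary",
    "region_summary",
    "density_correlation",
    "distribution_summary",
    "colocalization_ratio",
]

#: Fixed column order of nearest-neighbor tables.
NN_TABLE_COLUMNS = [
    "source_id",
    "source_class",
    "target_class",
    "nearest_target_id",
    "distance_um",
    "source_volume_mm3",
    "target_volume_mm3",
]

_CENTROID_COLS = ["centroid_z_um", "centroid_y_um", "centroid_x_um"]

#: Above this many targets a k-d tree is used; results are identical to
#: brute force because ties are re-resolved by lowest target id.
_KDTREE_THRESHOLD = 1000


def _centroids(table: pd.DataFrame) -> np.ndarray:
    pts = table[_CENTROID_COLS].to_numpy(dtype=float)
    if pts.size and not np.all(np.isfinite(pts)):
        raise ValueError("centroids must be finite")
    return pts


def nn_distances(
    sources: pd.DataFrame,
    targets: pd.DataFrame,
    exclude_self: bool = False,
) -> pd.DataFrame:
    """Nearest target for every source object.

    Ties in distance are broken by the lower target ``object_id``. When
    sources and targets are the same class, ``exclude_self=True`` is
    required and each object is barred from being its own neighbor. A
    source with no eligible target gets a missing (NaN) distance.
    """
    src_pts = _centroids(sources)
    tgt_pts = _centroids(targets)
    src_ids = sources["object_id"].to_numpy()
    tgt_ids = targets["object_id"].to_numpy()
    src_class = sources["class"].iloc[0] if len(sources) else "generic"
    tgt_class = targets["class"].iloc[0] if len(targets) else "generic"

    same_table = (
        len(sources) == len(targets)
        and len(sources) > 0
        and src_class == tgt_class
        and np.array_equal(np.sort(src_ids), np.sort(tgt_ids))
    )
    if same_table and not exclude_self:
        raise ValueError(
            "sources and targets are the same object set; pass exclude_self=True"
        )

    # Sort targets by id so that np.argmin's first-occurrence rule
    # implements the lowest-id tie-break.
    order = np.argsort(tgt_ids, kind="stable")
    tgt_ids_s = tgt_ids[order]
    tgt_pts_s = tgt_pts[order]
    tgt_vol_s = targets["volume_mm3"].to_numpy()[order] if len(targets) else np.empty(0)

    n, m = len(src_pts), len(tgt_pts_s)
    nearest_id = np.full(n, -1, dtype=np.int64)
    dist = np.full(n, np.nan)
    tgt_vol = np.full(n, np.nan)

    if m > 0 and n > 0:
        if m <= _KDTREE_THRESHOLD:
            d = cdist(src_pts, tgt_pts_s)
            if exclude_self and same_table:
                for i in range(n):
                    d[i, tgt_ids_s == src_ids[i]] = np.inf
            j = np.argmin(d, axis=1)
            dmin = d[np.arange(n), j]
            ok = np.isfinite(dmin)
            nearest_id[ok] = tgt_ids_s[j[ok]]
            dist[ok] = dmin[ok]
            tgt_vol[ok] = tgt_vol_s[j[ok]]
        else:
            tree = cKDTree(tgt_pts_s)
            k = 2 if (exclude_self and same_table) else 1
            dd, jj = tree.query(src_pts, k=max(k, 1))
            dd = np.atleast_2d(dd.T).T
            jj = np.atleast_2d(jj.T).T
            for i in range(n):
                cand_d = None
                for col in range(dd.shape[1]):
                    if exclude_self and same_table and tgt_ids_s[jj[i, col]] == src_ids[i]:
                        continue
                    cand_d = dd[i, col]
                    break
                if cand_d is None or not np.isfinite(cand_d):
                    continue
                # re-resolve ties by lowest id among all targets at cand_d
                ball = tree.query_ball_point(src_pts[i], cand_d * (1 + 1e-12) + 1e-9)
                best_j = -1
                for j2 in sorted(ball, key=lambda t: tgt_ids_s[t]):
                    if exclude_self and same_table and tgt_ids_s[j2] == src_ids[i]:
                        continue
                    dj = float(np.linalg.norm(src_pts[i] - tgt_pts_s[j2]))
                    if dj <= cand_d:
                        best_j = j2
                        break
                if best_j < 0:
                    best_j = int(jj[i, 0])
                nearest_id[i] = tgt_ids_s[best_j]
                dist[i] = float(np.linalg.norm(src_pts[i] - tgt_pts_s[best_j]))
                tgt_vol[i] = tgt_vol_s[best_j]

    table = pd.DataFrame(
        {
            "source_id": src_ids,
            "source_class": src_class,
            "target_class": tgt_class,
            "nearest_target_id": pd.array(
                [i if i >= 0 else None for i in nearest_id], dtype="Int64"
            ),
            "distance_um": dist,
            "source_volume_mm3": sources["volume_mm3"].to_numpy()
            if len(sources)
            else np.empty(0),
            "target_volume_mm3": tgt_vol,
        }
    )
    return table[NN_TABLE_COLUMNS]


def volume_distance_join(metastases: pd.DataFrame, tls: pd.DataFrame) -> pd.DataFrame:
    """One row per metastasis with its nearest-TLS distance and both volumes.

    Supports the "metastasis volume vs. distance to nearest TLS" view;
    with no TLS at all, every distance is missing and summaries report 0
    eligible rows.
    """
    return nn_distances(metastases, tls, exclude_self=False)


def volume_distance_summary(nntable: pd.DataFrame, radius_um: float | None = None) -> dict:
    """Summaries of a volume–distance join, with explicit eligibility counts."""
    eligible = nntable["distance_um"].notna()
    out = {
        "n_total": int(len(nntable)),
        "n_eligible": int(eligible.sum()),
        "n_missing_distance": int((~eligible).sum()),
        "mean_source_volume_mm3": float(nntable["source_volume_mm3"].mean())
        if len(nntable)
        else float("nan"),
    }
    sub = nntable[eligible]
    out["mean_distance_um"] = float(sub["distance_um"].mean()) if len(sub) else float("nan")
    out["median_distance_um"] = (
        float(sub["distance_um"].median()) if len(sub) else float("nan")
    )
    out["mean_nearest_target_volume_mm3"] = (
        float(sub["target_volume_mm3"].mean()) if len(sub) else float("nan")
    )
    if radius_um is not None:
        within = sub[sub["distance_um"] <= radius_um]
        out["radius_um"] = float(radius_um)
        out["n_within_radius"] = int(len(within))
        out["mean_source_volume_within_radius_mm3"] = (
            float(within["source_volume_mm3"].mean()) if len(within) else float("nan")
        )
    return out


def region_summary(objects: pd.DataFrame, regions: LabelVolume) -> pd.DataFrame:
    """Counts, densities and fractions of objects per organ region.

    Region membership is decided by the voxel containing each object's
    centroid; centroids falling on background are assigned to "none"
    rather than dropped. Fractions per class sum to 1 over all rows
    including "none".
    """
    spacing = np.asarray(regions.spacing_um)
    origin = np.asarray(regions.origin_um)
    shape = np.asarray(regions.shape)
    voxel_vol_mm3 = regions.voxel_volume_um3 / 1e9

    region_labels = sorted(int(v) for v in np.unique(regions.data) if v != 0)
    names = [regions.name_of(v) for v in region_labels] + ["none"]
    label_counts = np.bincount(regions.data.ravel(), minlength=max(region_labels, default=0) + 1)
    volumes = [label_counts[v] * voxel_vol_mm3 for v in region_labels]
    volumes.append(label_counts[0] * voxel_vol_mm3)  # background volume

    classes = sorted(objects["class"].unique()) if len(objects) else []
    assigned: dict[int, str] = {}
    if len(objects):
        pts = _centroids(objects)
        idx = np.floor((pts - origin) / spacing).astype(np.int64)
        idx = np.clip(idx, 0, shape - 1)
        memb = regions.data[idx[:, 0], idx[:, 1], idx[:, 2]]
        memb_names = [regions.name_of(int(v)) for v in memb]
    else:
        memb_names = []

    rows = []
    for name, vol in zip(names, volumes):
        row = {"region": name, "region_volume_mm3": float(vol)}
        for cls in classes:
            in_cls = (objects["class"] == cls).to_numpy()
            cnt = sum(
                1 for rn, ic in zip(memb_names, in_cls) if ic and rn == name
            )
            total = int(in_cls.sum())
            row[f"count_{cls}"] = cnt
            row[f"density_per_mm3_{cls}"] = cnt / vol if vol > 0 else float("nan")
            row[f"fraction_{cls}"] = cnt / total if total > 0 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def density_correlation(
    region_table: pd.DataFrame,
    class_a: str,
    class_b: str,
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlation between two classes' region densities.

    The "none" (background) row is excluded; at least 3 real regions
    with defined densities are required. Zero variance in either density
    vector is an error (correlation undefined).
    """
    sub = region_table[region_table["region"] != "none"]
    a = sub[f"density_per_mm3_{class_a}"].to_numpy(dtype=float)
    b = sub[f"density_per_mm3_{class_b}"].to_numpy(dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 3:
        raise ValueError(f"need >= 3 regions with defined densities, got {len(a)}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("density correlation undefined: zero variance in one class")
    if method == "pearson":
        r, p = stats.pearsonr(a, b)
    elif method == "spearman":
        r, p = stats.spearmanr(a, b)
    else:
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    return float(r), float(p)


def distribution_summary(values, cutoffs=()) -> dict:
    """Mean ± s.d., median, and empirical CDF at the given cutoffs.

    Missing (NaN) values are excluded with the exclusion count reported;
    an empty set after exclusion is an error.
    """
    arr = np.asarray(values, dtype=float).ravel()
    finite = np.isfinite(arr)
    excluded = int((~finite).sum())
    arr = arr[finite]
    if arr.size == 0:
        raise ValueError("distribution_summary: no finite values after exclusion")
    out = {
        "n": int(arr.size),
        "n_excluded": excluded,
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "median": float(np.median(arr)),
        "fraction_le": {float(c): float(np.mean(arr <= c)) for c in cutoffs},
    }
    return out


def colocalization_ratio(
    mask_a: LabelVolume, mask_b: LabelVolume, tolerance_um: float = 0.0
) -> float:
    """Fraction of mask-a foreground within ``tolerance_um`` of mask-b foreground.

    Tolerance 0 reduces to the plain voxel-overlap fraction. Distances
    are between voxel centers in physical units, computed with an exact
    Euclidean distance transform using the per-axis spacing.
    """
    check_same_geometry(mask_a, mask_b)
    if not (mask_a.is_binary() and mask_b.is_binary()):
        raise ValueError("colocalization requires binary masks")
    if tolerance_um < 0:
        raise ValueError("tolerance_um must be >= 0")
    a = mask_a.data.astype(bool)
    b = mask_b.data.astype(bool)
    n_a = int(a.sum())
    if n_a == 0:
        raise ValueError("mask_a is empty: colocalization ratio undefined")
    if tolerance_um == 0:
        return float((a & b).sum() / n_a)
    if not b.any():
        return 0.0
    dt = distance_transform_edt(~b, sampling=mask_a.spacing_um)
    return float((a & (dt <= tolerance_um)).sum() / n_a)
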