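"""Seed-based functional connectivity of preprocessed BOLD series.

The module consumes 4D data that has already been spatially
preprocessed (slice timing, realignment, normalization, smoothing are
upstream concerns) and covers the temporal and statistical stages:
motion-based subject exclusion, linear detrending with 0.01–0.1 Hz
band-pass filtering, voxelwise Pearson correlation with the mean seed
time course (Fisher-z transformed for group statistics), voxelwise
one-way ANOVA / two-sample t contrasts, and cluster-extent
thresholding of the resulting p maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import stats as _stats
from skimage.measure import label as _cc_label

__all__ = [
    "MOTION_PARAMS",
    "MotionQCResult",
    "BoldDataset",
    "SeedFCMap",
    "GroupStatMaps",
    "Cluster",
    "ClusterResult",
    "motion_qc",
    "detrend_and_bandpass",
    "seed_fc_map",
    "group_compare_maps",
    "cluster_threshold",
]

MOTION_PARAMS = ("tx_mm", "ty_mm", "tz_mm", "rx_deg", "ry_deg", "rz_deg")
_TRANSLATIONS = MOTION_PARAMS[:3]
_ROTATIONS = MOTION_PARAMS[3:]

#: clip bound applied to r before arctanh so z stays finite
_R_CLIP = 1.0 - 1e-7

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


@dataclass
class MotionQCResult:
    passed: bool
    offending: pd.DataFrame
    max_translation_mm: float
    max_rotation: float

    def __bool__(self) -> bool:
        return self.passed


def motion_qc(
    motion: pd.DataFrame,
    max_translation_mm: float = 1.0,
    max_rotation: float = 2.0,
) -> MotionQCResult:
    """Head-motion exclusion check on a six-parameter motion table.

    A subject fails if any volume's |translation| exceeds
    ``max_translation_mm`` on any axis, or any |rotation| exceeds
    ``max_rotation`` (degrees by convention) on any axis.
    """
    missing = [c for c in MOTION_PARAMS if c not in motion.columns]
    if missing:
        raise ValueError(f"motion table missing columns {missing}")
    params = motion[list(MOTION_PARAMS)].to_numpy(dtype=float)
    if not np.all(np.isfinite(params)):
        raise ValueError("motion table contains non-finite values")

    trans_bad = np.abs(motion[list(_TRANSLATIONS)].to_numpy(float)) > max_translation_mm
    rot_bad = np.abs(motion[list(_ROTATIONS)].to_numpy(float)) > max_rotation
    bad_rows = trans_bad.any(axis=1) | rot_bad.any(axis=1)
    return MotionQCResult(
        passed=not bad_rows.any(),
        offending=motion.loc[bad_rows],
        max_translation_mm=max_translation_mm,
        max_rotation=max_rotation,
    )


def detrend_and_bandpass(
    series: np.ndarray,
    repetition_time: float,
    band: tuple[float, float] = (0.01, 0.1),
    axis: int = -1,
    order: int = 4,
) -> np.ndarray:
    """Linear detrend followed by a zero-phase Butterworth band-pass.

    Applied along ``axis`` (time).  The output is mean-free since DC is
    outside the pass band.

    Raises
    ------
    ValueError
        If fewer than 10 timepoints, or the band is infeasible for the
        sampling rate (upper edge must be below Nyquist).
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[axis]
    if n < 10:
        raise ValueError(f"need at least 10 timepoints, got {n}")
    low, high = band
    nyquist = 0.5 / repetition_time
    if not 0.0 < low < high < nyquist:
        raise ValueError(
            f"band {band} Hz infeasible at repetition time {repetition_time} s "
            f"(Nyquist {nyquist} Hz)"
        )
    detrended = _signal.detrend(series, axis=axis, type="linear")
    sos = _signal.butter(order, band, btype="bandpass", fs=1.0 / repetition_time,
                         output="sos")
    return _signal.sosfiltfilt(sos, detrended, axis=axis)


@dataclass
class BoldDataset:
    """A single subject's preprocessed BOLD run with masks and motion."""

    data: np.ndarray
    repetition_time: float
    brain_mask: np.ndarray
    seed_mask: np.ndarray
    motion: pd.DataFrame | None = None
    subject_id: str = "sub"
    group: str | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        self.seed_mask = np.asarray(self.seed_mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4D (x, y, z, time)")
        spatial = self.data.shape[:3]
        if self.brain_mask.shape != spatial or self.seed_mask.shape != spatial:
            raise ValueError("masks must match the spatial shape of the data")
        if np.any(self.seed_mask & ~self.brain_mask):
            raise ValueError("seed mask must lie inside the brain mask")
        if not self.seed_mask.any():
            raise ValueError("seed mask is empty")
        if self.data.shape[3] < 10:
            raise ValueError("need at least 10 timepoints")


@dataclass
class SeedFCMap:
    """One subject's voxelwise seed-correlation map (r and Fisher z)."""

    subject_id: str
    r_map: np.ndarray
    z_map: np.ndarray
    group: str | None = None


def seed_fc_map(
    dataset: BoldDataset,
    band: tuple[float, float] | None = (0.01, 0.1),
) -> SeedFCMap:
    """Correlate every brain voxel's time course with the seed reference.

    The reference is the mean (detrended, band-passed) time course over
    the seed mask.  ``band=None`` skips filtering for series that are
    already filtered.  r is clipped to ±(1 − 1e−7) before the Fisher
    transform so z stays finite; in-mask voxels whose series has zero
    variance get NaN (their correlation is undefined).

    Raises
    ------
    ValueError
        If the seed reference has zero variance.
    """
    mask = dataset.brain_mask
    series = dataset.data[mask]  # (V, T)
    if band is not None:
        series = detrend_and_bandpass(series, dataset.repetition_time, band=band, axis=-1)

    seed_in_mask = dataset.seed_mask[mask]
    reference = series[seed_in_mask].mean(axis=0)
    reference = reference - reference.mean()
    ref_norm = float(np.sqrt(reference @ reference))
    if ref_norm == 0.0:
        raise ValueError("seed reference time course has zero variance")

    centered = series - series.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("vt,vt->v", centered, centered))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (centered @ reference) / (norms * ref_norm)
    r = np.clip(r, -1.0, 1.0)
    r[norms == 0] = np.nan

    r_map = np.full(mask.shape, np.nan)
    r_map[mask] = r
    z_map = np.full(mask.shape, np.nan)
    z_map[mask] = np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))
    return SeedFCMap(subject_id=dataset.subject_id, r_map=r_map, z_map=z_map,
                     group=dataset.group)


@dataclass
class GroupStatMaps:
    """Voxelwise group statistics over subjects' Fisher-z maps."""

    groups: tuple[str, ...]
    mask: np.ndarray
    f_map: np.ndarray
    f_p_map: np.ndarray
    pair_t_maps: dict = field(default_factory=dict)
    pair_p_maps: dict = field(default_factory=dict)


def _stack_group(maps: Sequence[np.ndarray | SeedFCMap], mask: np.ndarray) -> np.ndarray:
    rows = []
    for m in maps:
        arr = m.z_map if isinstance(m, SeedFCMap) else np.asarray(m, dtype=float)
        if arr.shape != mask.shape:
            raise ValueError("map shape does not match mask shape")
        rows.append(arr[mask])
    return np.asarray(rows)


def group_compare_maps(
    maps_by_group: Mapping[str, Sequence[np.ndarray | SeedFCMap]],
    mask: np.ndarray,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> GroupStatMaps:
    """Voxelwise one-way ANOVA across groups plus pairwise t contrasts.

    All statistics are computed on Fisher-z maps over a common mask.
    Voxels with no variance anywhere (all subjects identical) are
    reported with NaN statistic and p = 1.

    Parameters
    ----------
    maps_by_group
        Group label -> list of 3D z maps (or :class:`SeedFCMap`), at
        least 2 groups with at least 3 maps each.
    pairs
        Group pairs for pooled-variance two-sample t tests; defaults to
        all unordered pairs in group order.
    """
    groups = tuple(maps_by_group)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    mask = np.asarray(mask, dtype=bool)
    stacked = {g: _stack_group(maps_by_group[g], mask) for g in groups}
    for g, arr in stacked.items():
        if arr.shape[0] < 3:
            raise ValueError(f"group {g!r} has {arr.shape[0]} maps; need at least 3")

    # constant voxels (e.g. clipped seed self-correlations) are legitimate
    # degenerate inputs here; their statistics are guarded to p = 1 below
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        f_stat, f_p = _stats.f_oneway(*stacked.values(), axis=0)
    f_p = np.where(np.isfinite(f_p), f_p, 1.0)

    def to_map(values: np.ndarray) -> np.ndarray:
        out = np.full(mask.shape, np.nan)
        out[mask] = values
        return out

    result = GroupStatMaps(
        groups=groups,
        mask=mask,
        f_map=to_map(f_stat),
        f_p_map=to_map(f_p),
    )

    if pairs is None:
        pairs = [(groups[i], groups[j]) for i in range(len(groups))
                 for j in range(i + 1, len(groups))]
    for ga, gb in pairs:
        if ga not in stacked or gb not in stacked:
            raise ValueError(f"pair ({ga!r}, {gb!r}) references an unknown group")
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t_stat, t_p = _stats.ttest_ind(stacked[ga], stacked[gb], axis=0,
                                           equal_var=True)
        t_p = np.where(np.isfinite(t_p), t_p, 1.0)
        result.pair_t_maps[(ga, gb)] = to_map(np.asarray(t_stat))
        result.pair_p_maps[(ga, gb)] = to_map(np.asarray(t_p))
    return result


@dataclass
class Cluster:
    """A surviving suprathreshold connected component."""

    voxels: np.ndarray  # (size, 3) indices
    size: int
    peak_stat: float
    peak_location: tuple[int, int, int]
    sign: int  # +1 or -1


@dataclass
class ClusterResult:
    clusters: list
    voxel_p: float
    min_cluster_size: int
    connectivity: int

    def __len__(self) -> int:
        return len(self.clusters)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "cluster_id": i + 1,
                "size": c.size,
                "peak_stat": c.peak_stat,
                "x": c.peak_location[0],
                "y": c.peak_location[1],
                "z": c.peak_location[2],
                "sign": c.sign,
            }
            for i, c in enumerate(self.clusters)
        ]
        return pd.DataFrame(
            rows, columns=["cluster_id", "size", "peak_stat", "x", "y", "z", "sign"]
        )


def cluster_threshold(
    p_map: np.ndarray,
    stat_map: np.ndarray,
    voxel_p: float = 0.005,
    min_cluster_size: int = 50,
    connectivity: int = 18,
    mask: np.ndarray | None = None,
) -> ClusterResult:
    """Voxel-p plus cluster-extent thresholding of a voxelwise stat map.

    Voxels with ``p < voxel_p`` are binarized separately for positive
    and negative effects (sign of ``stat_map``), connected components
    are labeled under the chosen 3D neighborhood (6, 18 or 26; default
    18), and only components whose size is *strictly greater* than
    ``min_cluster_size`` survive.  Clusters are sorted by size
    (descending).
    """
    if connectivity not in _CONNECTIVITY:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY)}")
    p_map = np.asarray(p_map, dtype=float)
    stat_map = np.asarray(stat_map, dtype=float)
    if p_map.shape != stat_map.shape:
        raise ValueError("p map and stat map shapes differ")
    if mask is None:
        mask = np.isfinite(p_map)
    else:
        mask = np.asarray(mask, dtype=bool) & np.isfinite(p_map)

    with np.errstate(invalid="ignore"):
        supra = (p_map < voxel_p) & mask

    clusters: list[Cluster] = []
    for sign in (+1, -1):
        signed = supra & ((stat_map > 0) if sign > 0 else (stat_map < 0))
        if not signed.any():
            continue
        labels = _cc_label(signed, connectivity=_CONNECTIVITY[connectivity])
        for lab in range(1, labels.max() + 1):
            component = labels == lab
            size = int(component.sum())
            if size <= min_cluster_size:
                continue
            voxels = np.argwhere(component)
            stats_here = stat_map[component]
            peak_idx = int(np.argmax(np.abs(stats_here)))
            clusters.append(
                Cluster(
                    voxels=voxels,
                    size=size,
                    peak_stat=float(stats_here[peak_idx]),
                    peak_location=tuple(int(v) for v in voxels[peak_idx]),
                    sign=sign,
                )
            )
    clusters.sort(key=lambda c: c.size, reverse=True)
    return ClusterResult(
        clusters=clusters,
        voxel_p=voxel_p,
        min_cluster_size=min_cluster_size,
        connectivity=connectivity,
    )
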