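"""Regional PET quantification: VOI means and cerebellar-reference SUVR.

The uptake table is a tidy :class:`pandas.DataFrame` with one row per
subject: ``subject_id``, ``group``, then one column per region
(reference region included).  ``table.attrs`` carries the reference
region name and a ``normalized`` flag (SUV vs SUVR).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EmptyVOIError",
    "extract_voi_means",
    "compute_suvr",
    "region_columns",
    "read_uptake_table",
    "write_uptake_table",
]

_META_COLUMNS = ("subject_id", "group")


class EmptyVOIError(ValueError):
    """A requested atlas label has no voxels (or no finite voxels)."""


def region_columns(table: pd.DataFrame) -> list[str]:
    """Region columns of an uptake table (everything but the metadata)."""
    return [c for c in table.columns if c not in _META_COLUMNS]


def extract_voi_means(
    image: np.ndarray,
    atlas: np.ndarray,
    label_map: Mapping[int, str],
) -> dict[str, float]:
    """Mean image intensity per VOI defined by an integer label atlas.

    Image and atlas must be co-registered, voxel-aligned volumes of the
    same shape; no resampling is performed.  Non-finite image voxels
    (e.g. NaN margins from registration) are excluded from the mean,
    with the excluded count logged.

    Parameters
    ----------
    image
        3D scalar uptake volume.
    atlas
        3D integer label volume of the same shape.
    label_map
        Mapping from atlas label value to region name.

    Returns
    -------
    dict
        Region name -> mean uptake, in ``label_map`` iteration order.
    """
    image = np.asarray(image, dtype=float)
    atlas = np.asarray(atlas)
    if image.shape != atlas.shape:
        raise ValueError(
            f"image shape {image.shape} does not match atlas shape {atlas.shape}"
        )

    means: dict[str, float] = {}
    for label, region in label_map.items():
        voxels = image[atlas == int(label)]
        if voxels.size == 0:
            raise EmptyVOIError(f"region {region!r} (label {label}) has no voxels in atlas")
        finite = voxels[np.isfinite(voxels)]
        if finite.size == 0:
            raise EmptyVOIError(
                f"region {region!r} (label {label}) has no finite voxels"
            )
        dropped = voxels.size - finite.size
        if dropped:
            logger.info("region %s: excluded %d non-finite voxels", region, dropped)
        means[region] = float(finite.mean())
    return means


def compute_suvr(table: pd.DataFrame, reference: str | None = None) -> pd.DataFrame:
    """Normalize every region by the subject's reference-region uptake.

    After normalization the reference column is exactly 1 for every
    subject and ``attrs["normalized"]`` is set.  Ratios are unitless, so
    SUVR is invariant to any positive rescaling of a subject's SUVs.

    Raises
    ------
    ValueError
        If the reference column is missing, or any subject's reference
        value is non-positive or non-finite (the offending subject is
        named; no partial output is produced).
    """
    if reference is None:
        reference = table.attrs.get("reference_region")
    if reference is None or reference not in table.columns:
        raise ValueError(f"reference region {reference!r} not found in table")

    ref = table[reference].to_numpy(dtype=float)
    bad = ~np.isfinite(ref) | (ref <= 0)
    if np.any(bad):
        subjects = table.loc[bad, "subject_id"].tolist()
        raise ValueError(
            f"non-positive or missing reference uptake for subjects {subjects}"
        )

    out = table.copy()
    regions = region_columns(table)
    out[regions] = table[regions].to_numpy(dtype=float) / ref[:, None]
    out.attrs = dict(table.attrs)
    out.attrs["normalized"] = True
    out.attrs["reference_region"] = reference
    return out


def write_uptake_table(table: pd.DataFrame, path) -> None:
    """Write the table as CSV: ``subject_id, group, <regions...>``."""
    table.to_csv(path, index=False, lineterminator="\n")


def read_uptake_table(path, reference: str | None = None) -> pd.DataFrame:
    """Read an uptake CSV written by :func:`write_uptake_table`."""
    table = pd.read_csv(Path(path), float_precision="round_trip")
    for col in _META_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"uptake table missing required column {col!r}")
    if reference is not None:
        if reference not in table.columns:
            raise ValueError(f"reference region {reference!r} not found in table")
        table.attrs["reference_region"] = reference
    table.attrs.setdefault("normalized", False)
    return table
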