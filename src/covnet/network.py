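"""Inter-subject metabolic covariance networks.

A group's network is the region × region matrix of Pearson correlations
of regional uptake computed *across subjects*: an edge is strong when
two regions' uptake co-varies over animals, the PET analogue of
functional connectivity.  Requires at least 3 subjects per group.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ZeroVarianceError", "GroupNetwork", "pearson_r", "build_group_network",
           "correlation_matrix", "read_network", "write_network"]


class ZeroVarianceError(ValueError):
    """Correlation is undefined because one input has zero variance."""


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson product–moment correlation of two sequences.

    Raises
    ------
    ValueError
        On unequal lengths or fewer than 3 observations.
    ZeroVarianceError
        If either sequence is constant (the correlation is undefined and
        must not silently become 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations for a correlation")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = float(np.sqrt(dx @ dx))
    sy = float(np.sqrt(dy @ dy))
    if sx == 0.0 or sy == 0.0:
        raise ZeroVarianceError("zero variance input: correlation undefined")
    r = float((dx @ dy) / (sx * sy))
    return min(1.0, max(-1.0, r))


def correlation_matrix(data: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation matrix of an (n_subjects, K) array.

    Columns with zero variance produce NaN rows/columns (flagged-missing
    edges) rather than raising, so callers can carry the flag forward.
    """
    x = np.asarray(data, dtype=float)
    centered = x - x.mean(axis=0)
    norms = np.sqrt(np.einsum("ij,ij->j", centered, centered))
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = centered / norms
        corr = unit.T @ unit
    corr = np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    bad = norms == 0
    corr[bad, :] = np.nan
    corr[:, bad] = np.nan
    np.fill_diagonal(corr, np.where(bad, np.nan, np.diag(corr)))
    return corr


@dataclass
class GroupNetwork:
    """One group's metabolic network: regions, correlation matrix, n."""

    group: str
    regions: tuple[str, ...]
    matrix: np.ndarray
    n_subjects: int
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.regions = tuple(self.regions)
        self.matrix = np.asarray(self.matrix, dtype=float)
        k = len(self.regions)
        if self.matrix.shape != (k, k):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match {k} regions"
            )

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def edge(self, region_i: str, region_j: str) -> float:
        i = self.regions.index(region_i)
        j = self.regions.index(region_j)
        return float(self.matrix[i, j])


def build_group_network(
    table: pd.DataFrame,
    regions: Sequence[str],
    group: str | None = None,
) -> GroupNetwork:
    """Build the inter-subject correlation network for one group.

    Parameters
    ----------
    table
        Uptake table rows; if ``group`` is given, rows are filtered to
        that group first, otherwise all rows are used (and must belong
        to a single group).
    regions
        Ordered region subset to correlate (typically the ten analysis
        VOIs, excluding the reference region).

    Returns
    -------
    GroupNetwork
        Symmetric, unit-diagonal matrix; edges touching a zero-variance
        region are NaN (flagged-missing) with a warning, never imputed.
    """
    if group is not None:
        table = table[table["group"] == group]
    else:
        present = table["group"].unique()
        if len(present) != 1:
            raise ValueError(
                f"table mixes groups {list(present)}; pass group= to select one"
            )
        group = str(present[0])

    missing = [r for r in regions if r not in table.columns]
    if missing:
        raise ValueError(f"regions {missing} not present in table")
    n = len(table)
    if n < 3:
        raise ValueError(f"group {group!r} has {n} subjects; need at least 3")

    data = table[list(regions)].to_numpy(dtype=float)
    corr = correlation_matrix(data)

    flags = {}
    constant = [r for r, sd in zip(regions, data.std(axis=0)) if sd == 0]
    if constant:
        warnings.warn(
            f"group {group!r}: zero-variance regions {constant}; "
            "their edges are flagged missing",
            stacklevel=2,
        )
        flags["zero_variance_regions"] = constant
    return GroupNetwork(group=group, regions=tuple(regions), matrix=corr,
                        n_subjects=n, flags=flags)


def write_network(network: GroupNetwork, path) -> None:
    """CSV matrix with region header row/column, plus a JSON sidecar."""
    path = Path(path)
    frame = pd.DataFrame(network.matrix, index=network.regions, columns=network.regions)
    frame.to_csv(path, index_label="region", lineterminator="\n")
    sidecar = {
        "group": network.group,
        "n_subjects": network.n_subjects,
        "flags": network.flags,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_network(path) -> GroupNetwork:
    path = Path(path)
    frame = pd.read_csv(path, index_col=0)
    sidecar_path = path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return GroupNetwork(
        group=meta.get("group", path.stem),
        regions=tuple(frame.columns),
        matrix=frame.to_numpy(dtype=float),
        n_subjects=int(meta.get("n_subjects", 3)),
        flags=meta.get("flags", {}),
    )
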