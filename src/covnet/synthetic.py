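"""Synthetic PET cohorts and toy BOLD datasets with known ground truth.

The generators emulate the data layout of a four-arm rat imaging study
(sham/stroke crossed with standard/enriched housing): per-group regional
FDG uptake tables over ten hippocampal–cortical volumes of interest plus
a cerebellar reference, and small 4D BOLD volumes containing voxel
clusters with a prescribed population correlation to a seed time course.

Uptake is drawn from a multivariate normal whose correlation matrix is
the specification's target (after positive-semidefinite repair), so the
downstream Pearson-correlation machinery can be checked against exact
ground truth.  BOLD cluster voxels are a calibrated mixture
``r * s + sqrt(1 - r^2) * e`` of the standardized seed signal ``s`` and
an independent standardized band-limited noise series ``e``, which makes
the population voxel–seed correlation exactly ``r``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

__all__ = [
    "CohortSpec",
    "FmriSimSpec",
    "FmriDataset",
    "repair_correlation",
    "generate_uptake_cohort",
    "generate_fmri_dataset",
    "study_cohort_spec",
    "DEFAULT_REGIONS",
    "DEFAULT_REFERENCE",
]

#: The ten analysis VOIs: hippocampus, dentate gyrus, entorhinal,
#: cingulate and retrosplenial cortex in both hemispheres.
DEFAULT_REGIONS: tuple[str, ...] = (
    "Hip_L", "Hip_R",
    "DG_L", "DG_R",
    "Ent_L", "Ent_R",
    "Cg_L", "Cg_R",
    "RSC_L", "RSC_R",
)

DEFAULT_REFERENCE = "cerebellum"

MOTION_COLUMNS = ("volume", "tx_mm", "ty_mm", "tz_mm", "rx_deg", "ry_deg", "rz_deg")


def repair_correlation(matrix: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Project a symmetric unit-diagonal matrix onto the valid correlation matrices.

    Negative eigenvalues are clipped at zero and the result is rescaled
    back to unit diagonal.  The operation is idempotent on matrices that
    are already positive semi-definite.

    Parameters
    ----------
    matrix
        Square symmetric matrix with unit diagonal and entries in [-1, 1].
    tol
        Symmetry / diagonal tolerance for input validation.

    Returns
    -------
    numpy.ndarray
        The nearest (in the eigenvalue-clipping sense) positive
        semi-definite correlation matrix.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"correlation matrix must be square, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=1e-6):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=1e-6):
        raise ValueError("correlation matrix must have unit diagonal")

    m = 0.5 * (m + m.T)
    eigval, eigvec = np.linalg.eigh(m)
    if eigval[0] >= -tol:
        out = m.copy()
    else:
        clipped = np.clip(eigval, 0.0, None)
        out = (eigvec * clipped) @ eigvec.T
        d = np.sqrt(np.clip(np.diag(out), tol, None))
        out = out / np.outer(d, d)
        out = 0.5 * (out + out.T)
    np.fill_diagonal(out, 1.0)
    return out


def _as_per_group(value, group_names: Sequence[str], name: str) -> dict:
    """Broadcast a shared value to a per-group mapping."""
    if isinstance(value, Mapping):
        missing = set(group_names) - set(value)
        if missing:
            raise ValueError(f"{name} missing entries for groups {sorted(missing)}")
        return {g: value[g] for g in group_names}
    return {g: value for g in group_names}


@dataclass(frozen=True)
class CohortSpec:
    """Ground-truth description of a multi-group regional-uptake cohort.

    Parameters
    ----------
    group_names
        Study arm labels, e.g. ``("SS", "SE", "MS", "ME")``.
    n_per_group
        Subjects per group (single count or per-group mapping); at least
        3 for any group entering correlation estimation.
    region_names
        Ordered region list, *including* the reference region.
    reference_region
        Name of the reference region (must appear in ``region_names``).
    mean_uptake
        Per-region mean uptake (arbitrary SUV-like units); either one
        vector shared by all groups or a per-group mapping.
    correlation
        Target inter-subject correlation matrix over ``region_names``;
        one matrix or a per-group mapping.  Repaired to positive
        semi-definite before sampling.
    noise_sd
        Per-region marginal standard deviation (scalar broadcasts).
    seed
        RNG seed; each group draws from an independent substream so that
        appending a group never perturbs earlier groups.
    """

    group_names: tuple[str, ...]
    n_per_group: int | Mapping[str, int]
    region_names: tuple[str, ...]
    mean_uptake: Sequence[float] | Mapping[str, Sequence[float]]
    correlation: np.ndarray | Mapping[str, np.ndarray]
    noise_sd: float | Sequence[float] = 0.25
    reference_region: str = DEFAULT_REFERENCE
    seed: int = 0

    def __post_init__(self):
        if len(set(self.group_names)) != len(self.group_names):
            raise ValueError("group names must be unique")
        if len(set(self.region_names)) != len(self.region_names):
            raise ValueError("region names must be unique")
        if self.reference_region not in self.region_names:
            raise ValueError(
                f"reference region {self.reference_region!r} not in region_names"
            )
        for g, n in self.n_by_group().items():
            if n < 3:
                raise ValueError(f"group {g!r} has n={n}; need at least 3 subjects")

    def n_by_group(self) -> dict[str, int]:
        if isinstance(self.n_per_group, Mapping):
            return {g: int(self.n_per_group[g]) for g in self.group_names}
        return {g: int(self.n_per_group) for g in self.group_names}

    def means_by_group(self) -> dict[str, np.ndarray]:
        out = {}
        for g, mu in _as_per_group(self.mean_uptake, self.group_names, "mean_uptake").items():
            mu = np.asarray(mu, dtype=float)
            if mu.shape != (len(self.region_names),):
                raise ValueError(
                    f"mean_uptake for group {g!r} has shape {mu.shape}; "
                    f"expected ({len(self.region_names)},)"
                )
            out[g] = mu
        return out

    def correlations_by_group(self) -> dict[str, np.ndarray]:
        out = {}
        for g, r in _as_per_group(self.correlation, self.group_names, "correlation").items():
            r = np.asarray(r, dtype=float)
            k = len(self.region_names)
            if r.shape != (k, k):
                raise ValueError(
                    f"correlation for group {g!r} has shape {r.shape}; expected ({k}, {k})"
                )
            if np.any(np.abs(r) > 1 + 1e-9):
                raise ValueError(f"correlation entries for group {g!r} outside [-1, 1]")
            out[g] = repair_correlation(r)
        return out

    def sds(self) -> np.ndarray:
        sd = np.broadcast_to(np.asarray(self.noise_sd, dtype=float), (len(self.region_names),))
        if np.any(sd <= 0):
            raise ValueError("noise_sd must be strictly positive")
        return np.asarray(sd)


def generate_uptake_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a subject × region uptake table from a :class:`CohortSpec`.

    Each group contributes ``n_per_group`` rows from a multivariate
    normal with the group's mean vector and covariance
    ``diag(sd) @ R @ diag(sd)``.  Deterministic given ``spec.seed``.

    Returns
    -------
    pandas.DataFrame
        Columns ``subject_id, group, <region_1..K>`` (reference region
        included as an ordinary column).
    """
    means = spec.means_by_group()
    corrs = spec.correlations_by_group()
    ns = spec.n_by_group()
    sd = spec.sds()

    root = np.random.SeedSequence(spec.seed)
    streams = root.spawn(len(spec.group_names))

    frames = []
    for g, child in zip(spec.group_names, streams):
        rng = np.random.default_rng(child)
        cov = corrs[g] * np.outer(sd, sd)
        draws = rng.multivariate_normal(means[g], cov, size=ns[g], method="eigh")
        frame = pd.DataFrame(draws, columns=list(spec.region_names))
        frame.insert(0, "group", g)
        frame.insert(0, "subject_id", [f"{g}{i + 1:02d}" for i in range(ns[g])])
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    table.attrs["reference_region"] = spec.reference_region
    table.attrs["normalized"] = False
    return table


def study_cohort_spec(
    seed: int = 0,
    n_per_group: int = 8,
    regions: Sequence[str] = DEFAULT_REGIONS,
    reference: str = DEFAULT_REFERENCE,
) -> CohortSpec:
    """The default four-arm study conditions for simulation work.

    Arms: SS (sham/standard), SE (sham/enriched), MS (stroke/standard),
    ME (stroke/enriched), eight subjects each.  Within-network coupling
    is strong in sham arms (r = 0.75), collapses after stroke under
    standard housing (r = 0.15) and partially recovers under enrichment
    (r = 0.55); right-hemisphere hippocampal/parahippocampal uptake is
    depressed ~15% in MS and ~7% in ME relative to sham, mirroring the
    lesioned hemisphere.  The cerebellar reference stays uncoupled from
    the analysis network and unaffected in mean.
    """
    regions = tuple(regions)
    all_regions = regions + (reference,) if reference not in regions else regions
    k = len(all_regions)
    ref_idx = all_regions.index(reference)
    net_idx = [i for i in range(k) if i != ref_idx]

    def corr(r_within: float) -> np.ndarray:
        m = np.eye(k)
        for a in net_idx:
            for b in net_idx:
                if a != b:
                    m[a, b] = r_within
        return m

    base_mean = np.full(k, 2.2)
    base_mean[ref_idx] = 2.0
    lesioned = [
        i for i, name in enumerate(all_regions)
        if name.endswith("_R") and name.split("_")[0] in ("Hip", "Ent", "Cg")
    ]

    def mean_with_deficit(frac: float) -> np.ndarray:
        mu = base_mean.copy()
        mu[lesioned] *= 1.0 - frac
        return mu

    return CohortSpec(
        group_names=("SS", "SE", "MS", "ME"),
        n_per_group=n_per_group,
        region_names=all_regions,
        reference_region=reference,
        mean_uptake={
            "SS": base_mean,
            "SE": base_mean,
            "MS": mean_with_deficit(0.15),
            "ME": mean_with_deficit(0.07),
        },
        correlation={
            "SS": corr(0.75),
            "SE": corr(0.75),
            "MS": corr(0.15),
            "ME": corr(0.55),
        },
        noise_sd=0.25,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Toy BOLD data


@dataclass(frozen=True)
class FmriSimSpec:
    """Description of a toy 4D BOLD dataset with planted seed-coupled clusters.

    ``seed_voxels`` share one standardized band-limited signal; each
    entry of ``cluster_specs`` is a ``(voxel index array, target r)``
    pair whose voxels mix that signal with independent band-limited
    noise so their population correlation to the seed equals the target.
    All remaining in-mask voxels are independent noise.
    """

    volume_shape: tuple[int, int, int]
    n_timepoints: int = 300
    repetition_time: float = 1.0
    seed_voxels: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), int))
    cluster_specs: tuple[tuple[np.ndarray, float], ...] = ()
    noise_sd: float = 1.0
    band: tuple[float, float] = (0.01, 0.1)
    motion_excursions: tuple[tuple[int, str, float], ...] = ()
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "volume_shape", tuple(int(s) for s in self.volume_shape))
        if len(self.volume_shape) != 3 or any(s < 1 for s in self.volume_shape):
            raise ValueError("volume_shape must be three positive voxel counts")
        if self.n_timepoints < 10:
            raise ValueError("need at least 10 timepoints")
        object.__setattr__(self, "seed_voxels", _check_voxels(self.seed_voxels, self.volume_shape))
        checked = []
        for voxels, r in self.cluster_specs:
            if not -1.0 < r < 1.0:
                raise ValueError(f"cluster target correlation {r} not in (-1, 1)")
            checked.append((_check_voxels(voxels, self.volume_shape), float(r)))
        object.__setattr__(self, "cluster_specs", tuple(checked))
        nyquist = 0.5 / self.repetition_time
        if not 0 < self.band[0] < self.band[1] < nyquist:
            raise ValueError(
                f"band {self.band} infeasible for repetition time {self.repetition_time}"
            )


def _check_voxels(voxels: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    v = np.atleast_2d(np.asarray(voxels, dtype=int))
    if v.size == 0:
        return np.zeros((0, 3), int)
    if v.shape[1] != 3:
        raise ValueError("voxel sets must be (n, 3) index arrays")
    if np.any(v < 0) or np.any(v >= np.asarray(shape)):
        raise ValueError("voxel indices outside volume_shape")
    return v


@dataclass
class FmriDataset:
    """In-memory bundle: 4D data, masks, repetition time, motion table."""

    data: np.ndarray
    repetition_time: float
    brain_mask: np.ndarray
    seed_mask: np.ndarray
    motion: pd.DataFrame


def _bandlimited_noise(rng: np.random.Generator, n: int, size: int, tr: float,
                       band: tuple[float, float]) -> np.ndarray:
    """``size`` independent standardized band-limited series of length ``n``."""
    white = rng.standard_normal((size, n))
    sos = _signal.butter(4, band, btype="bandpass", fs=1.0 / tr, output="sos")
    filtered = _signal.sosfiltfilt(sos, white, axis=-1)
    filtered -= filtered.mean(axis=-1, keepdims=True)
    sdev = filtered.std(axis=-1, ddof=0, keepdims=True)
    return filtered / sdev


def generate_fmri_dataset(spec: FmriSimSpec) -> FmriDataset:
    """Build the toy BOLD dataset described by an :class:`FmriSimSpec`.

    Raises
    ------
    ValueError
        If the seed voxel set overlaps any cluster, or clusters overlap
        each other.
    """
    shape = spec.volume_shape
    taken = {tuple(v) for v in spec.seed_voxels}
    for voxels, _ in spec.cluster_specs:
        vset = {tuple(v) for v in voxels}
        if taken & vset:
            raise ValueError("seed and cluster voxel sets overlap")
        taken |= vset

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    t = spec.n_timepoints
    seed_signal = _bandlimited_noise(rng, t, 1, spec.repetition_time, spec.band)[0]

    data = np.empty(shape + (t,), dtype=np.float64)
    noise = rng.standard_normal(shape + (t,))
    data[:] = spec.noise_sd * noise

    for x, y, z in spec.seed_voxels:
        data[x, y, z] = spec.noise_sd * seed_signal
    for voxels, r in spec.cluster_specs:
        eta = _bandlimited_noise(rng, t, len(voxels), spec.repetition_time, spec.band)
        mixed = r * seed_signal + math.sqrt(1.0 - r * r) * eta
        for (x, y, z), series in zip(voxels, mixed):
            data[x, y, z] = spec.noise_sd * series

    brain_mask = np.ones(shape, dtype=bool)
    seed_mask = np.zeros(shape, dtype=bool)
    for x, y, z in spec.seed_voxels:
        seed_mask[x, y, z] = True

    motion = pd.DataFrame(0.0, index=range(t), columns=list(MOTION_COLUMNS))
    motion["volume"] = np.arange(t)
    for vol, col, value in spec.motion_excursions:
        if col not in MOTION_COLUMNS[1:]:
            raise ValueError(f"unknown motion column {col!r}")
        motion.loc[vol, col] = value

    return FmriDataset(
        data=data,
        repetition_time=spec.repetition_time,
        brain_mask=brain_mask,
        seed_mask=seed_mask,
        motion=motion,
    )


def write_fmri_dataset(dataset: FmriDataset, out_dir, prefix: str = "sub") -> dict:
    """Write a dataset as NIfTI-1 volumes plus a motion TSV; return the paths."""
    import nibabel as nib
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)

    img = nib.Nifti1Image(dataset.data.astype(np.float32), affine)
    img.header.set_zooms((1.0, 1.0, 1.0, dataset.repetition_time))
    paths = {
        "bold": out / f"{prefix}_bold.nii.gz",
        "brain_mask": out / f"{prefix}_brain_mask.nii.gz",
        "seed_mask": out / f"{prefix}_seed_mask.nii.gz",
        "motion": out / f"{prefix}_motion.tsv",
    }
    nib.save(img, paths["bold"])
    nib.save(nib.Nifti1Image(dataset.brain_mask.astype(np.int16), affine), paths["brain_mask"])
    nib.save(nib.Nifti1Image(dataset.seed_mask.astype(np.int16), affine), paths["seed_mask"])
    dataset.motion.to_csv(paths["motion"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
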