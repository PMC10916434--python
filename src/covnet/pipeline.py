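"""End-to-end runners for the PET and fMRI analysis arms.

Each run is driven by a validated config (JSON-loadable pydantic
model), writes every artifact through the declared file formats
(CSV/TSV/JSON/NIfTI), and records a manifest with the config hash and
seed so a run can be replayed exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from covnet import fmri as _fmri
from covnet.inference import PermutationConfig, permutation_edge_test, permutation_metric_test
from covnet.network import build_group_network, write_network
from covnet.quantify import compute_suvr, extract_voi_means, read_uptake_table, write_uptake_table
from covnet.synthetic import DEFAULT_REFERENCE, DEFAULT_REGIONS

logger = logging.getLogger(__name__)

__all__ = ["PetRunConfig", "FmriRunConfig", "run_pet_arm", "run_fmri_arm"]


class PetImageEntry(BaseModel):
    subject_id: str
    group: str
    path: str


class PetRunConfig(BaseModel):
    """Configuration of the PET arm: quantify -> networks -> inference."""

    table: Optional[str] = None
    images: list[PetImageEntry] = Field(default_factory=list)
    atlas: Optional[str] = None
    labels: Optional[str] = None
    regions: list[str] = Field(default_factory=lambda: list(DEFAULT_REGIONS))
    reference: str = DEFAULT_REFERENCE
    use: str = "suv"  # which quantity feeds the networks: "suv" or "suvr"
    comparisons: list[tuple[str, str]] = Field(default_factory=list)
    n_permutations: int = 10_000
    alpha: float = 0.05
    tail: str = "two-sided"
    exhaustive: str = "auto"
    out_dir: str = "covnet_pet_out"
    seed: int = 0

    @field_validator("use")
    @classmethod
    def _check_use(cls, v: str) -> str:
        if v not in ("suv", "suvr"):
            raise ValueError("use must be 'suv' or 'suvr'")
        return v

    @classmethod
    def from_json(cls, path) -> "PetRunConfig":
        return cls.model_validate_json(Path(path).read_text())


class FmriSubjectEntry(BaseModel):
    subject_id: str
    group: str
    bold: str
    brain_mask: str
    seed_mask: str
    motion: Optional[str] = None


class FmriRunConfig(BaseModel):
    """Configuration of the fMRI arm: QC -> FC maps -> group stats -> clusters."""

    subjects: list[FmriSubjectEntry]
    repetition_time: Optional[float] = None  # fall back to the NIfTI header
    band: tuple[float, float] = (0.01, 0.1)
    max_translation_mm: float = 1.0
    max_rotation: float = 2.0
    voxel_p: float = 0.005
    min_cluster_size: int = 50
    connectivity: int = 18
    comparisons: list[tuple[str, str]] = Field(default_factory=list)
    out_dir: str = "covnet_fmri_out"
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "FmriRunConfig":
        return cls.model_validate_json(Path(path).read_text())


def _config_hash(config: BaseModel) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _setup_run_logger(out_dir: Path) -> logging.Logger:
    run_logger = logging.getLogger(f"covnet.run.{out_dir}")
    run_logger.setLevel(logging.INFO)
    run_logger.handlers.clear()
    run_logger.addHandler(logging.FileHandler(out_dir / "run.log", mode="w"))
    run_logger.addHandler(logging.StreamHandler())
    run_logger.propagate = False
    return run_logger


def _write_manifest(out_dir: Path, config: BaseModel, outputs: dict) -> None:
    manifest = {
        "config": config.model_dump(mode="json"),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _derive_seed(base: int, index: int) -> int:
    return int(np.random.SeedSequence([base, index]).generate_state(1)[0] % (2**31))


def _quantify_images(config: PetRunConfig, log: logging.Logger) -> pd.DataFrame:
    import nibabel as nib

    if not config.atlas or not config.labels:
        raise ValueError("image-based runs need both 'atlas' and 'labels'")
    atlas = np.asanyarray(nib.load(config.atlas).dataobj)
    label_map = {int(k): v for k, v in json.loads(Path(config.labels).read_text()).items()}
    rows = []
    for entry in config.images:
        image = np.asanyarray(nib.load(entry.path).dataobj)
        means = extract_voi_means(image, atlas, label_map)
        rows.append({"subject_id": entry.subject_id, "group": entry.group, **means})
        log.info("quantified %s (%s)", entry.subject_id, entry.group)
    table = pd.DataFrame(rows)
    table.attrs["reference_region"] = config.reference
    table.attrs["normalized"] = False
    return table


def run_pet_arm(config: PetRunConfig) -> dict:
    """Run the full PET arm and write all artifacts to ``config.out_dir``.

    Stages: quantification (if images are given, else the uptake table
    is read), optional SUVR normalization, per-group network
    construction, edge-wise permutation tests with FDR per comparison,
    and a global-efficiency permutation test per comparison.

    Returns a dict of output paths plus the in-memory results
    (``table``, ``networks``, ``edge_tests``, ``metric_tests``).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = _setup_run_logger(out_dir)
    t0 = time.perf_counter()
    outputs: dict = {}

    try:
        if config.images:
            table = _quantify_images(config, log)
        elif config.table:
            table = read_uptake_table(config.table, reference=config.reference)
        else:
            raise ValueError("config must provide either 'table' or 'images'")
    except Exception:
        log.exception("stage 'quantify' failed")
        raise

    if config.use == "suvr":
        table = compute_suvr(table, reference=config.reference)
        log.info("normalized uptake to SUVR (reference %s)", config.reference)
    table_path = out_dir / "uptake_table.csv"
    write_uptake_table(table, table_path)
    outputs["table"] = table_path

    regions = [r for r in config.regions if r != config.reference]
    networks = {}
    for group in table["group"].unique():
        try:
            net = build_group_network(table, regions, group=str(group))
        except Exception:
            log.exception("stage 'network' failed for group %s", group)
            raise
        networks[str(group)] = net
        net_path = out_dir / f"{group}_network.csv"
        write_network(net, net_path)
        outputs[f"network_{group}"] = net_path
        log.info("built network for group %s (n=%d)", group, net.n_subjects)

    edge_tests, metric_tests = {}, {}
    for idx, (group_a, group_b) in enumerate(config.comparisons):
        for g in (group_a, group_b):
            if g not in networks:
                raise ValueError(f"comparison group {g!r} not present in table")
        perm = PermutationConfig(
            n_permutations=config.n_permutations,
            alpha=config.alpha,
            tail=config.tail,
            exhaustive=config.exhaustive,
            seed=_derive_seed(config.seed, 2 * idx),
        )
        table_a = table[table["group"] == group_a]
        table_b = table[table["group"] == group_b]
        try:
            edges = permutation_edge_test(table_a, table_b, regions, config=perm)
            metric = permutation_metric_test(
                table_a, table_b, regions,
                config=PermutationConfig(
                    n_permutations=config.n_permutations,
                    alpha=config.alpha,
                    tail=config.tail,
                    exhaustive=config.exhaustive,
                    seed=_derive_seed(config.seed, 2 * idx + 1),
                ),
            )
        except Exception:
            log.exception("stage 'inference' failed for %s vs %s", group_a, group_b)
            raise
        edge_tests[(group_a, group_b)] = edges
        metric_tests[(group_a, group_b)] = metric

        tag = f"{group_a}_vs_{group_b}"
        edges_path = out_dir / f"{tag}_edges.tsv"
        edges.to_csv(edges_path, sep="\t", index=False, lineterminator="\n")
        outputs[f"edges_{tag}"] = edges_path
        metric_path = out_dir / f"{tag}_efficiency.json"
        metric_path.write_text(json.dumps(metric.to_dict(), indent=2, sort_keys=True) + "\n")
        outputs[f"efficiency_{tag}"] = metric_path
        log.info(
            "%s vs %s: %d/%d FDR-significant edges; E_global %.4f vs %.4f (p=%.4g)",
            group_a, group_b, int(edges["significant"].sum()), len(edges),
            metric.value_a, metric.value_b, metric.p_perm,
        )

    _write_manifest(out_dir, config, outputs)
    log.info("PET arm finished in %.1f s", time.perf_counter() - t0)
    return {
        **outputs,
        "table_data": table,
        "networks": networks,
        "edge_tests": edge_tests,
        "metric_tests": metric_tests,
    }


def _load_bold_subject(entry: FmriSubjectEntry, repetition_time: float | None) -> _fmri.BoldDataset:
    import nibabel as nib

    img = nib.load(entry.bold)
    data = np.asanyarray(img.dataobj, dtype=float)
    if repetition_time is None:
        zooms = img.header.get_zooms()
        repetition_time = float(zooms[3]) if len(zooms) > 3 else 1.0
    brain = np.asanyarray(nib.load(entry.brain_mask).dataobj) > 0
    seed = np.asanyarray(nib.load(entry.seed_mask).dataobj) > 0
    motion = pd.read_csv(entry.motion, sep="\t") if entry.motion else None
    return _fmri.BoldDataset(
        data=data,
        repetition_time=repetition_time,
        brain_mask=brain,
        seed_mask=seed,
        motion=motion,
        subject_id=entry.subject_id,
        group=entry.group,
    )


def run_fmri_arm(config: FmriRunConfig) -> dict:
    """Run the fMRI arm: motion QC, per-subject FC maps, group statistics,
    cluster-extent thresholding.

    Subjects failing motion QC are excluded (and logged), mirroring the
    acquisition-time exclusion rule; the run continues with the rest.
    Returns output paths plus in-memory ``fc_maps``, ``group_stats``,
    ``cluster_results`` and the ``excluded`` subject list.
    """
    import nibabel as nib

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = _setup_run_logger(out_dir)
    t0 = time.perf_counter()
    outputs: dict = {}

    fc_maps: dict[str, list[_fmri.SeedFCMap]] = {}
    excluded: list[str] = []
    mask_ref: np.ndarray | None = None
    for entry in config.subjects:
        dataset = _load_bold_subject(entry, config.repetition_time)
        if dataset.motion is not None:
            qc = _fmri.motion_qc(
                dataset.motion,
                max_translation_mm=config.max_translation_mm,
                max_rotation=config.max_rotation,
            )
            if not qc.passed:
                excluded.append(entry.subject_id)
                log.info(
                    "excluded %s: motion exceeded limits on %d volumes",
                    entry.subject_id, len(qc.offending),
                )
                continue
        if mask_ref is None:
            mask_ref = dataset.brain_mask
        elif not np.array_equal(mask_ref, dataset.brain_mask):
            raise ValueError(f"brain mask of {entry.subject_id} differs from the others")
        fc = _fmri.seed_fc_map(dataset, band=config.band)
        fc_maps.setdefault(entry.group, []).append(fc)
        z_path = out_dir / f"{entry.subject_id}_z.nii.gz"
        nib.save(nib.Nifti1Image(fc.z_map.astype(np.float32), np.eye(4)), z_path)
        outputs[f"zmap_{entry.subject_id}"] = z_path
        log.info("FC map written for %s (%s)", entry.subject_id, entry.group)

    usable = {g: maps for g, maps in fc_maps.items() if len(maps) >= 3}
    group_stats = None
    cluster_results: dict = {}
    if len(usable) >= 2 and mask_ref is not None:
        pairs = [tuple(p) for p in config.comparisons] or None
        group_stats = _fmri.group_compare_maps(usable, mask_ref, pairs=pairs)
        nib.save(nib.Nifti1Image(np.nan_to_num(group_stats.f_map).astype(np.float32),
                                 np.eye(4)), out_dir / "anova_F.nii.gz")
        outputs["anova_F"] = out_dir / "anova_F.nii.gz"
        for (ga, gb), t_map in group_stats.pair_t_maps.items():
            p_map = group_stats.pair_p_maps[(ga, gb)]
            clusters = _fmri.cluster_threshold(
                p_map, t_map,
                voxel_p=config.voxel_p,
                min_cluster_size=config.min_cluster_size,
                connectivity=config.connectivity,
                mask=mask_ref,
            )
            cluster_results[(ga, gb)] = clusters
            tag = f"{ga}_vs_{gb}"
            cl_path = out_dir / f"{tag}_clusters.tsv"
            clusters.to_dataframe().to_csv(cl_path, sep="\t", index=False,
                                           lineterminator="\n")
            outputs[f"clusters_{tag}"] = cl_path
            log.info("%s: %d surviving clusters", tag, len(clusters))
    else:
        log.info("fewer than 2 groups with >= 3 usable subjects; skipping group stats")

    _write_manifest(out_dir, config, outputs)
    log.info("fMRI arm finished in %.1f s (excluded: %s)", time.perf_counter() - t0,
             excluded or "none")
    return {
        **outputs,
        "fc_maps": fc_maps,
        "group_stats": group_stats,
        "cluster_results": cluster_results,
        "excluded": excluded,
    }
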