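"""End-to-end pipeline orchestration and population reporting.

A single config drives: LAC map → object identification → compartment
segmentation → morphometry → population summary.  Outputs (label
volumes, per-object CSV, summary JSON, meshes) are a pure function of
the input volume, the config and the seed, so a rerun with the same
config reproduces them byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .compartments import (
    CompartmentSegmentation,
    seeds_from_masks,
    segment_object,
    train_pixel_classifier,
)
from .grid import Units, VoxelGrid3D
from .identify import MitoObject, identify_objects, objects_to_labels
from .io import RunConfig, read_volume, records_to_frame, write_report, write_volume
from .lac import absorbance_to_lac
from .morphometry import (
    MCI_RESOLVABLE_THRESHOLD,
    MorphometryRecord,
    classify_complexity,
    export_mesh,
    measure_object,
)
from .phantom import PhantomSpec, apply_optics, make_phantom


class ConfigValidationError(ValueError):
    """The pipeline config is missing or mis-specifies a required field."""


@dataclass
class PipelineRun:
    """Everything one pipeline execution produced, with provenance."""

    config: dict
    records: list[MorphometryRecord]
    segmentations: list[CompartmentSegmentation]
    objects: list[MitoObject]
    summary: dict
    timings: dict[str, float]
    lac_volume: VoxelGrid3D
    version: str = __version__


REQUIRED_RUN_FIELDS = ("lac_window", "size_window")


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigValidationError("config must be a mapping or a YAML file path")
    if "phantom" not in config and "input" not in config:
        raise ConfigValidationError("config needs a 'phantom' or 'input' section")
    run = config.get("run")
    if not isinstance(run, dict):
        raise ConfigValidationError("config missing 'run' section")
    for fld in REQUIRED_RUN_FIELDS:
        if fld not in run:
            raise ConfigValidationError(f"config missing required run field '{fld}'")
    return config


def run_pipeline(config, output_dir: str | Path | None = None) -> PipelineRun:
    """Execute LAC → identify → segment → measure → summarize.

    ``config`` is a mapping (or YAML path) with a ``run`` section
    (:class:`~sxtmorph.io.RunConfig` fields; ``lac_window`` and
    ``size_window`` must be explicit) and either a ``phantom`` section
    (:class:`~sxtmorph.phantom.PhantomSpec` fields) or an ``input``
    section (``path``, ``units``, optional ``voxel_size``, optional
    ``seeds`` path for classifier training annotations).

    If ``output_dir`` is given, writes ``labels.mrc``, ``objects.csv``,
    ``summary.json``, per-object segmentations under ``seg/`` and
    meshes under ``meshes/``.
    """
    config = _load_config(config)
    cfg = RunConfig.from_dict(config["run"])
    timings: dict[str, float] = {}

    def timed(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                timings[name] = time.perf_counter() - self.t0

        return _T()

    # -- stage 1: LAC volume ----------------------------------------
    truth = None
    with timed("lac"):
        if "phantom" in config:
            spec = PhantomSpec(**config["phantom"])
            truth = make_phantom(spec)
            lac = apply_optics(
                truth.lac_volume, spec.psf_fwhm, spec.noise_scale, seed=spec.seed
            )
        else:
            inp = config["input"]
            grid = read_volume(
                inp["path"], units=inp.get("units", "LAC_per_um"),
                voxel_size_override=inp.get("voxel_size"),
            )
            lac = absorbance_to_lac(grid) if grid.units is Units.ABSORBANCE else grid

    # -- stage 2: identify -------------------------------------------
    with timed("identify"):
        objects = identify_objects(lac, cfg)

    # -- stage 3: segment --------------------------------------------
    with timed("segment"):
        classifier = None
        if objects:
            seeds = _training_seeds(config, lac, truth, cfg)
            classifier = train_pixel_classifier(lac, seeds, cfg)
        segmentations = [
            segment_object(lac, obj.mask, classifier, cfg, object_id=obj.object_id)
            for obj in objects
        ]

    # -- stage 4: measure --------------------------------------------
    with timed("measure"):
        records = []
        for obj, seg in zip(objects, segmentations):
            rec = measure_object(seg, lac, lac.voxel_size, cfg)
            records.append(rec)

    # -- stage 5: summarize ------------------------------------------
    with timed("summarize"):
        summary = summarize_run(records) if records else {"n_objects": 0}

    run = PipelineRun(
        config={"run": cfg.to_dict(), **{k: v for k, v in config.items() if k != "run"}},
        records=records,
        segmentations=segmentations,
        objects=objects,
        summary=summary,
        timings=timings,
        lac_volume=lac,
    )
    if output_dir is not None:
        _write_outputs(run, Path(output_dir), cfg)
    return run


def _training_seeds(config, lac, truth, cfg) -> np.ndarray:
    """Sparse class annotations: from a seeds volume, or phantom truth."""
    inp = config.get("input", {})
    if "seeds" in inp:
        return read_volume(inp["seeds"], units=Units.LABEL).data
    if truth is not None:
        cristae = np.zeros(lac.shape, dtype=bool)
        matrix = np.zeros(lac.shape, dtype=bool)
        for obj in truth.objects:
            cristae |= obj.cristae_mask
            matrix |= obj.matrix_mask
        return seeds_from_masks(cristae, matrix, rng=cfg.seed)
    raise ConfigValidationError(
        "config missing required input field 'seeds' (no phantom truth available)"
    )


def _write_outputs(run: PipelineRun, out: Path, cfg: RunConfig) -> None:
    out.mkdir(parents=True, exist_ok=True)
    lac = run.lac_volume
    labels = objects_to_labels(run.objects, lac.shape)
    labels.voxel_size = lac.voxel_size
    write_volume(labels, out / "labels.mrc")
    write_report(run.records, out / "objects.csv", decimals=cfg.report_decimals)

    seg_dir = out / "seg"
    mesh_dir = out / "meshes"
    seg_dir.mkdir(exist_ok=True)
    mesh_dir.mkdir(exist_ok=True)
    for seg in run.segmentations:
        comp = np.zeros(lac.shape, dtype=np.int32)
        comp[seg.cristae_label] = 1
        comp[seg.matrix_label] = 2
        write_volume(
            VoxelGrid3D(comp, voxel_size=lac.voxel_size, units=Units.LABEL),
            seg_dir / f"object_{seg.object_id:03d}.mrc",
        )
        for name, mask in (("cristae", seg.cristae_label), ("matrix", seg.matrix_label)):
            if mask.any():
                export_mesh(
                    mask, lac.voxel_size,
                    mesh_dir / f"object_{seg.object_id:03d}_{name}.stl",
                    cfg.mesh_smoothing_sigma,
                )

    (out / "summary.json").write_text(json.dumps(_jsonable(run.summary), indent=2))
    (out / "config.json").write_text(json.dumps(_jsonable(run.config), indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# population summary
# ---------------------------------------------------------------------------

def summarize_run(
    records: list[MorphometryRecord],
    mci_threshold: float = MCI_RESOLVABLE_THRESHOLD,
) -> dict:
    """Mean ± sd of every table column, plus complexity counts.

    Volume-fraction means are computed from the per-object fractions,
    not from pooled volumes; sd uses the sample (n−1) convention.
    """
    if not records:
        raise ValueError("need at least one record")
    frame = records_to_frame(records)
    numeric = frame.drop(columns=["object_id"])
    stats = {}
    for col in numeric.columns:
        vals = numeric[col].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            continue
        stats[col] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            "n": int(vals.size),
        }
    n_resolvable = sum(
        1 for r in records if r.mci is not None and classify_complexity(r, mci_threshold) == "resolvable"
    )
    return {
        "n_objects": len(records),
        "columns": stats,
        "n_mci_resolvable": n_resolvable,
        "mci_threshold": mci_threshold,
        "volfrac_cristae_mean_pct": stats["volfrac_cristae_pct"]["mean"],
        "volfrac_matrix_mean_pct": stats["volfrac_matrix_pct"]["mean"],
    }
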