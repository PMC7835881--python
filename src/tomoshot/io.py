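"""File I/O and pipeline wiring: MRC2014 volumes (via gemmi), HDF5 bulk
subtomogram storage, JSON dataset manifests, YAML configuration, structured
logging, and the simulate -> train -> eval -> segment pipeline."""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.transform import Rotation

from .phantoms import DensityMap, Pose, make_phantom, phantom_library
from .simulate import (OpticsParams, SimulationConfig, SubtomogramRecord,
                       TomoDataset, build_dataset)

__all__ = [
    "read_volume", "write_volume", "save_dataset", "load_dataset",
    "load_manifest", "validate_manifest", "load_config", "config_hash",
    "run_pipeline", "setup_logging",
]

MANIFEST_FORMAT = 1
logger = logging.getLogger("tomoshot")


# --------------------------------------------------------------------------
# volumes (MRC2014)


def read_volume(path: str) -> tuple[np.ndarray, float]:
    """Read an MRC/CCP4 map; returns (volume, voxel size in Angstrom)."""
    import gemmi

    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(str(p))
    try:
        m = gemmi.read_ccp4_map(str(p))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"malformed MRC file {p}: {exc}") from exc
    vol = np.array(m.grid, copy=True)
    sp = m.grid.spacing
    if not np.allclose(sp, sp[0], rtol=1e-3):
        warnings.warn(f"anisotropic voxel sizes {sp} in {p}; using the first")
    return vol, float(sp[0])


def write_volume(volume: np.ndarray, path: str, voxel_size: float = 10.0) -> None:
    """Write a volume as an MRC2014 map with the voxel size in the header."""
    import gemmi

    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(volume, dtype=np.float32))
    n = volume.shape
    m.grid.unit_cell = gemmi.UnitCell(
        n[0] * voxel_size, n[1] * voxel_size, n[2] * voxel_size, 90, 90, 90
    )
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


# --------------------------------------------------------------------------
# dataset storage: HDF5 + JSON manifest


def _pose_to_json(pose: Pose) -> dict:
    quat = Rotation.from_matrix(pose.rotation).as_quat()  # (x, y, z, w)
    return {"quaternion": quat.tolist(), "translation": pose.translation.tolist()}


def _pose_from_json(d: dict) -> Pose:
    rot = Rotation.from_quat(d["quaternion"]).as_matrix()
    return Pose(rot, np.array(d["translation"]))


def save_dataset(dataset: TomoDataset, out_dir: str,
                 config_digest: str = "") -> Path:
    """Write dataset.h5 (volumes/masks/labels/splits) plus manifest.json."""
    import h5py

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h5_path = out / "dataset.h5"
    recs = dataset.records
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("volumes", data=np.stack([r.volume for r in recs]))
        f.create_dataset("masks",
                         data=np.stack([r.gt_mask for r in recs]).astype(np.uint8))
        f.create_dataset("labels",
                         data=[r.class_label.encode() for r in recs])
        f.create_dataset("splits", data=[r.split.encode() for r in recs])
        f.attrs["snr"] = dataset.snr
        f.attrs["seed"] = dataset.seed
        f.attrs["config_hash"] = config_digest
    manifest = {
        "format": MANIFEST_FORMAT,
        "seed": dataset.seed,
        "config_hash": config_digest,
        "snr": None if np.isinf(dataset.snr) else dataset.snr,
        "classes": dataset.class_names,
        "train_classes": dataset.train_classes,
        "test_classes": dataset.test_classes,
        "records": [
            {
                "path": "dataset.h5",
                "index": i,
                "class_label": r.class_label,
                "split": r.split,
                "snr": None if np.isinf(r.snr) else r.snr,
                "pose": _pose_to_json(r.pose),
            }
            for i, r in enumerate(recs)
        ],
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def load_manifest(path: str) -> dict:
    with open(path) as f:
        return json.load(f)


def validate_manifest(manifest: dict, base_dir: str = ".") -> dict:
    """Check split disjointness, file existence and label consistency."""
    errors: list[str] = []
    records = manifest.get("records", [])
    if not records:
        errors.append("no records")
    train = set(manifest.get("train_classes", []))
    test = set(manifest.get("test_classes", []))
    overlap = train & test
    if overlap:
        errors.append(f"classes in both splits: {sorted(overlap)}")
    registry = set(manifest.get("classes", []))
    counts: dict[str, int] = {}
    for r in records:
        label = r.get("class_label")
        counts[label] = counts.get(label, 0) + 1
        if label not in registry:
            errors.append(f"record label {label!r} missing from class registry")
        expected = "test" if label in test else "train"
        if r.get("split") != expected:
            errors.append(f"record of class {label!r} has split {r.get('split')!r}")
        if not (Path(base_dir) / r["path"]).exists():
            errors.append(f"missing file: {r['path']}")
    # each error kind reported once
    seen: set[str] = set()
    errors = [e for e in errors if not (e in seen or seen.add(e))]
    return {"ok": not errors, "errors": errors,
            "classes": sorted(counts), "per_class_counts": counts}


def load_dataset(manifest_path: str) -> TomoDataset:
    import h5py

    manifest = load_manifest(manifest_path)
    base = Path(manifest_path).parent
    report = validate_manifest(manifest, base)
    if not report["ok"]:
        raise ValueError("invalid manifest: " + "; ".join(report["errors"]))
    records: list[SubtomogramRecord] = []
    by_file: dict[str, list[dict]] = {}
    for r in manifest["records"]:
        by_file.setdefault(r["path"], []).append(r)
    for rel, recs in by_file.items():
        with h5py.File(base / rel, "r") as f:
            vols = f["volumes"][:]
            masks = f["masks"][:].astype(bool)
        for r in recs:
            i = r["index"]
            snr = np.inf if r["snr"] is None else float(r["snr"])
            records.append(SubtomogramRecord(
                vols[i], r["class_label"], masks[i],
                _pose_from_json(r["pose"]), snr, split=r["split"],
            ))
    snr = np.inf if manifest["snr"] is None else float(manifest["snr"])
    return TomoDataset(records, manifest["classes"], manifest["train_classes"],
                       manifest["test_classes"], snr, manifest["seed"])


# --------------------------------------------------------------------------
# configuration


def load_config(path: str) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _require(config: dict, key: str) -> dict:
    if key not in config:
        raise KeyError(f"missing config section: {key!r}")
    return config[key]


def simulation_config_from_dict(sim: dict, seed: int) -> SimulationConfig:
    sim = dict(sim)
    sim.pop("classes", None)
    optics = OpticsParams(**sim.pop("optics", {}))
    snr = sim.pop("snr", None)
    snr = np.inf if snr in (None, "inf") else float(snr)
    shape = tuple(sim.pop("tomogram_shape", (150, 150, 100)))
    return SimulationConfig(snr=snr, tomogram_shape=shape, optics=optics,
                            seed=seed, **sim)


def class_maps_from_config(sim: dict) -> list[DensityMap]:
    specs = sim.get("classes")
    if specs is None:
        return phantom_library()[:6]
    if isinstance(specs, int):
        return phantom_library()[:specs]
    size = sim.get("subtomo_size", 32)
    return [make_phantom(s, size) for s in specs]


# --------------------------------------------------------------------------
# pipeline


class _JsonLineHandler(logging.FileHandler):
    def emit(self, record):
        record.msg = json.dumps(
            {"level": record.levelname, "name": record.name,
             "message": record.getMessage()}
        )
        record.args = ()
        logging.FileHandler.emit(self, record)


def setup_logging(log_path: str | None = None, level: int = logging.INFO) -> None:
    logger.setLevel(level)
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        console = logging.StreamHandler()
        console.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(console)
    if log_path is not None:
        logger.addHandler(_JsonLineHandler(log_path))


def _variant_name(duse: bool, decoder: bool) -> str:
    base = "duse-scnn" if duse else "scnn"
    return base + ("+decoder" if decoder else "-nodecoder")


def run_pipeline(config: dict, out_dir: str, seed: int = 0) -> dict:
    """simulate -> train -> eval -> segment; emits dataset, checkpoint and
    metrics CSVs shaped like the accuracy and per-class DSC tables."""
    from .crf import CRFParams
    from .model import ModelConfig, save_checkpoint
    from .training import TrainConfig, evaluate_nway, train

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config_hash(config)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    artifacts: dict = {"config_hash": digest, "seed": seed}

    stage = "simulate"
    try:
        sim_cfg = _require(config, "sim")
        class_maps = class_maps_from_config(sim_cfg)
        sim = simulation_config_from_dict(sim_cfg, seed=seeds[0])
        dataset = build_dataset(sim, class_maps)
        artifacts["manifest"] = str(save_dataset(dataset, out, digest))
        logger.info("simulated %d records, classes=%s",
                    len(dataset.records), dataset.class_names)

        stage = "train"
        model_cfg = ModelConfig(seed=seeds[1], **_require(config, "model"))
        train_cfg = TrainConfig(seed=seeds[2], **_require(config, "train"))
        result = train(dataset, model_cfg, train_cfg)
        ckpt = out / "checkpoint.npz"
        save_checkpoint(result.model, ckpt)
        artifacts["checkpoint"] = str(ckpt)
        pd.DataFrame(result.loss_history).assign(
            config_hash=digest, seed=seed
        ).to_csv(out / "loss_history.csv", index=False)
        logger.info("trained %d epochs, final loss %.4f",
                    len(result.loss_history), result.loss_history[-1]["total"])

        stage = "eval"
        eval_cfg = _require(config, "eval")
        n_ways = eval_cfg.get("n_ways", [2])
        episodes = eval_cfg.get("episodes", 1000)
        crf = CRFParams(**eval_cfg.get("crf", {})) if eval_cfg.get(
            "crf_enabled", True) else None
        rng = np.random.default_rng(seeds[3])
        acc_rows, dsc_rows = [], []
        variant = _variant_name(model_cfg.duse_enabled, model_cfg.decoder_enabled)
        for n_way in n_ways:
            report = evaluate_nway(
                result.model, dataset, n_way, episodes, rng, crf_params=crf,
                max_dsc_records_per_class=eval_cfg.get("dsc_records_per_class"),
            )
            acc_rows.append({"snr": dataset.snr, "variant": variant,
                             "n_way": n_way, "accuracy": report.accuracy})
            for cls, (mean, std) in report.per_class_dsc.items():
                dsc_rows.append({"variant": variant, "n_way": n_way,
                                 "class": cls, "dsc_mean": mean, "dsc_std": std})
            logger.info("eval %d-way: accuracy %.3f", n_way, report.accuracy)
        meta = {"config_hash": digest, "seed": seed}
        acc_path = out / "metrics_accuracy.csv"
        pd.DataFrame(acc_rows, columns=["snr", "variant", "n_way", "accuracy"]
                     ).assign(**meta).to_csv(acc_path, index=False)
        artifacts["metrics_accuracy"] = str(acc_path)
        dsc_path = out / "metrics_dsc.csv"
        pd.DataFrame(
            dsc_rows,
            columns=["variant", "n_way", "class", "dsc_mean", "dsc_std"],
        ).assign(**meta).to_csv(dsc_path, index=False)
        artifacts["metrics_dsc"] = str(dsc_path)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return artifacts
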