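"""End-to-end orchestration: simulate -> build-matrix -> normalize ->
rsd / classify / pca, driven by one YAML config, with provenance capture.

Every run writes into a fresh ``run-NNN`` directory under the configured
output root; completed stage outputs are never overwritten. The manifest
records the config snapshot, seeds, and a SHA-256 digest for every artifact,
so re-running an identical config reproduces identical digests for the
deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import yaml

from . import __version__
from .binning import build_feature_matrix
from .classify import group_ellipse, pca_projection, run_cv
from .errors import ConfigurationError
from .matrix import BinDefinition, BinnedFeatureMatrix, read_matrix_table, read_metadata
from .normalize import NormalizationConfig, assign_batches, normalize_matrix
from .reproducibility import interbatch_rsd, intrabatch_rsd
from .simulate import CohortConfig, simulate_cohort, simulate_replicate_study
from .workflows import rsd_input_matrix

__all__ = ["RunManifest", "run_pipeline", "load_config"]

REGION_VOCABULARY = {"forehead", "cheek", "neck"}


@dataclass
class RunManifest:
    config: dict
    seed: int
    tool_version: str
    started: float
    run_dir: str
    outputs: dict[str, dict] = field(default_factory=dict)
    finished: float | None = None

    def record(self, name: str, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[name] = {"path": str(path), "sha256": digest}

    def write(self, path: Path) -> None:
        self.finished = time.time()
        path.write_text(json.dumps(self.__dict__, indent=2, default=str))


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError("config must be a YAML mapping")
    return cfg


def _validate_config(cfg: dict) -> None:
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ConfigurationError("config needs a 'simulate' or an 'inputs' section")
    for analysis in cfg.get("analyses", []):
        kind = analysis.get("type")
        if kind not in {"rsd", "classify", "pca"}:
            raise ConfigurationError(f"unknown analysis type {kind!r}")
        for key in ("region", "regions", "group_by"):
            val = analysis.get(key)
            vals = val if isinstance(val, (list, tuple)) else [val] if val else []
            for v in vals:
                if key != "group_by" and v not in REGION_VOCABULARY:
                    raise ConfigurationError(f"unknown region label {v!r}")


def _cohort_config(section: dict, seed: int) -> CohortConfig:
    kwargs = {k: v for k, v in section.items() if k != "kind"}
    if "regions" in kwargs:
        kwargs["regions"] = tuple(kwargs["regions"])
    if "region_effects" in kwargs:
        kwargs["region_effects"] = {
            r: tuple(v) for r, v in kwargs["region_effects"].items()
        }
    if "batch_multipliers" in kwargs and kwargs["batch_multipliers"] is not None:
        kwargs["batch_multipliers"] = tuple(kwargs["batch_multipliers"])
    kwargs.setdefault("rng_seed", seed)
    try:
        return CohortConfig(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(f"bad simulate section: {exc}") from exc


def _new_run_dir(root: Path) -> Path:
    root.mkdir(parents=True, exist_ok=True)
    n = 1
    while (root / f"run-{n:03d}").exists():
        n += 1
    run_dir = root / f"run-{n:03d}"
    run_dir.mkdir()
    return run_dir


def run_pipeline(config: dict | str | Path, out_root: str | Path | None = None) -> RunManifest:
    """Execute the configured stages in order and write a manifest.

    ``config`` is a mapping or a YAML path. Validation happens before any
    computation; a failing stage aborts with its name, leaving completed
    stage outputs intact.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    _validate_config(cfg)
    seed = int(cfg.get("seed", 0))
    root = Path(out_root if out_root is not None else cfg.get("out_dir", "runs"))
    run_dir = _new_run_dir(root)
    manifest = RunManifest(
        config=cfg, seed=seed, tool_version=__version__,
        started=time.time(), run_dir=str(run_dir),
    )

    # -- stage: input (simulate or load) -----------------------------------
    if "simulate" in cfg:
        sim_cfg = _cohort_config(cfg["simulate"], seed)
        kind = cfg["simulate"].get("kind", "cohort")
        if kind == "cohort":
            sim = simulate_cohort(sim_cfg)
        elif kind == "replicate":
            sim = simulate_replicate_study(sim_cfg)
        else:
            raise ConfigurationError(f"unknown simulate kind {kind!r}")
        spectra_dir = run_dir / "spectra"
        sim.write(spectra_dir, formats=cfg["simulate"].get("formats", ("ms1",)))
        metadata = sim.metadata
        manifest.record("metadata", spectra_dir / "metadata.tsv")
        bin_cfg = cfg.get("binning", {})
        bin_def = BinDefinition(
            mz_min=bin_cfg.get("mz_min", 250.0),
            mz_max=bin_cfg.get("mz_max", 1300.0),
            width=bin_cfg.get("bin_width", 0.01),
        )
        rt = (bin_cfg.get("rt_min", 0.8), bin_cfg.get("rt_max", 1.0))
        raw = build_feature_matrix(sim.spectra, metadata, bin_def, rt)
    else:
        inputs = cfg["inputs"]
        metadata = read_metadata(inputs["metadata"])
        raw = read_matrix_table(inputs["matrix"])  # bypasses binning
    raw_path = run_dir / "matrix_raw.tsv"
    raw.to_tsv(raw_path)
    manifest.record("matrix_raw", raw_path)

    # -- stage: normalize ---------------------------------------------------
    norm_section = cfg.get("normalize", {})
    norm_cfg = NormalizationConfig(
        min_nonzero_fraction=norm_section.get("min_nonzero_fraction", 0.01),
        epsilon=float(norm_section.get("epsilon", 1e-10)),
        n_keep_bins=norm_section.get("n_keep", 3000),
        batch_mode=norm_section.get("batch_mode", "blocks:30"),
    )
    stages = normalize_matrix(raw, metadata, norm_cfg, return_stages=True)
    final = stages["top_selected"]
    final_path = run_dir / "matrix_processed.tsv"
    final.to_tsv(final_path)
    manifest.record("matrix_processed", final_path)

    # -- stage: analyses ----------------------------------------------------
    for i, analysis in enumerate(cfg.get("analyses", []), start=1):
        kind = analysis["type"]
        out_path = run_dir / f"analysis_{i:02d}_{kind}.json"
        if kind == "rsd":
            result = _run_rsd(analysis, stages, metadata)
        elif kind == "classify":
            result = _run_classify(analysis, stages, metadata, norm_cfg, seed)
        else:
            result = _run_pca(analysis, final, metadata)
        out_path.write_text(json.dumps(result, indent=2))
        manifest.record(f"analysis_{i:02d}_{kind}", out_path)

    manifest_path = run_dir / "manifest.json"
    manifest.write(manifest_path)
    return manifest


def _run_rsd(analysis: dict, stages: dict, metadata) -> dict:
    mat = rsd_input_matrix(stages, analysis.get("scale", "tic"))
    mode = analysis.get("mode", "intrabatch")
    fn = {"intrabatch": intrabatch_rsd, "interbatch": interbatch_rsd}.get(mode)
    if fn is None:
        raise ConfigurationError(f"unknown rsd mode {mode!r}")
    regions = analysis.get("region")
    regions = [regions] if isinstance(regions, str) else (
        regions or sorted(metadata["region"].unique())
    )
    out = {"type": "rsd", "mode": mode, "scale": analysis.get("scale", "tic"), "regions": {}}
    for region in regions:
        summary = fn(mat, metadata, region)
        out["regions"][region] = {
            "median_percent_rsd": summary.median_percent_rsd,
            "n_groups": summary.n_groups,
            "n_excluded": summary.n_excluded,
        }
    return out


def _classification_matrix(analysis, stages, metadata, norm_cfg, sample_ids):
    """Re-run the chain on the analysis' sample subset (its own batch vector
    and bin selection), starting from the raw matrix."""
    raw = stages["raw"].select_samples(sample_ids)
    md = metadata[metadata["sample_id"].astype(str).isin(sample_ids)]
    batch = assign_batches(md, "column:batch") if "batch" in md.columns else None
    cfg = NormalizationConfig(
        min_nonzero_fraction=norm_cfg.min_nonzero_fraction,
        epsilon=norm_cfg.epsilon,
        n_keep_bins=analysis.get("n_keep", norm_cfg.n_keep_bins),
        batch_mode=norm_cfg.batch_mode,
    )
    return normalize_matrix(raw, md, cfg, batch=batch), md


def _run_classify(analysis: dict, stages: dict, metadata, norm_cfg, seed: int) -> dict:
    task = analysis.get("task", "sex")
    if task == "sex":
        md = metadata
        labels_col = "sex"
        positive = analysis.get("positive_class", "male")
    elif task == "region":
        regions = analysis.get("regions")
        if not regions or len(regions) != 2:
            raise ConfigurationError("region task needs exactly two regions")
        md = metadata[metadata["region"].isin(regions)]
        labels_col = "region"
        positive = analysis.get("positive_class", regions[0])
    else:
        raise ConfigurationError(f"unknown classify task {task!r}")
    ids = list(md["sample_id"].astype(str))
    matrix, md = _classification_matrix(analysis, stages, metadata, norm_cfg, ids)
    labels = md.set_index(md["sample_id"].astype(str)).loc[matrix.sample_ids, labels_col]
    result = run_cv(matrix, labels, md, seed=seed, positive_class=positive)
    return {
        "type": "classify",
        "task": task,
        "positive_class": result.positive_class,
        "n_samples": len(result.table),
        "accuracy_percent": result.accuracy,
        "auc": result.auc,
        "roc_points": result.roc_points.tolist(),
        "per_sample": result.table.to_dict(orient="records"),
        "seed": seed,
    }


def _run_pca(analysis: dict, final: BinnedFeatureMatrix, metadata) -> dict:
    group_by = analysis.get("group_by", "region")
    if group_by not in metadata.columns:
        raise ConfigurationError(f"metadata has no column {group_by!r}")
    pca = pca_projection(final, scale=analysis.get("scale", False))
    md = metadata.set_index(metadata["sample_id"].astype(str)).loc[pca.sample_ids]
    groups = md[group_by].astype(str).to_numpy()
    ellipses = group_ellipse(pca.scores, groups, level=analysis.get("ellipse_level", 0.95))
    return {
        "type": "pca",
        "group_by": group_by,
        "explained_variance_ratio": pca.explained_variance_ratio.tolist(),
        "scores": {
            sid: [float(pca.scores[i, 0]), float(pca.scores[i, 1])]
            for i, sid in enumerate(pca.sample_ids)
        },
        "ellipses": {
            g: {
                "center": e.center.tolist(),
                "semi_axes": e.semi_axes.tolist(),
                "angle_deg": e.angle_deg,
                "level": e.level,
            }
            for g, e in ellipses.items()
        },
    }
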