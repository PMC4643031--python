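"""Configured end-to-end experiments with logging and provenance.

``run_experiment`` wires the full workflow — scene simulation or input
loading, feature assembly, stratified splitting, training the configured
classifiers, prediction, majority-vote and/or Bayesian-average fusion,
accuracy assessment and uncertainty diagnostics, and optionally two-date
change detection — and writes every map, report and a machine-readable run
manifest (inputs, seeds, versions, timings) to an output directory.  A
rerun with the same configuration and seed reproduces the outputs exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .assess import (
    accuracy_report,
    cmp_histogram,
    confusion_matrix,
    proportion_ratio,
    sample_size_sensitivity,
)
from .change import class_area_change, conversion_matrix
from .classify import predict_proba, stratified_split, train_backend, KINDS
from .features import assemble_features
from .fusion import fuse_bayesian, fuse_majority
from .io import read_cube, read_map, read_raster, read_samples, write_map, write_raster
from .synthetic import (
    SceneConfig,
    ClassSignature,
    default_scene_config,
    sample_reference_points,
    simulate_scene,
)
from .types import LULCMap, ProbabilityCube

log = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "run_experiment", "load_config"]


class ConfigError(ValueError):
    """Invalid experiment configuration (reported before any compute)."""


@dataclass
class ExperimentConfig:
    """Declarative description of one classification experiment."""

    seed: int = 0
    combo: str = "C3"
    classifiers: tuple[str, ...] = ("rf", "svm", "wknn")
    hyperparams: dict[str, dict] = field(default_factory=dict)
    fusion: tuple[str, ...] = ("bayes", "vote")
    train_fraction: float = 0.7
    # synthetic-scene inputs (used unless explicit paths are given)
    scene: dict[str, Any] = field(default_factory=dict)
    n_per_class: int = 200
    homogeneity_window: int = 3
    # file inputs (cube + dem + samples GeoTIFF/CSV paths)
    inputs: dict[str, str] = field(default_factory=dict)
    classify_map: bool = True
    cmp_thresholds: tuple[float, ...] = (0.3, 0.4)
    ratio_flag_threshold: float = 3.0
    sensitivity: dict[str, Any] = field(default_factory=dict)
    change: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.classifiers:
            raise ConfigError("config lists no classifiers")
        bad = set(self.classifiers) - set(KINDS)
        if bad:
            raise ConfigError(f"unknown classifier kinds: {sorted(bad)}")
        if self.combo not in ("C1", "C2", "C3"):
            raise ConfigError(f"unknown feature combination {self.combo!r}")
        bad_fusion = set(self.fusion) - {"bayes", "vote"}
        if bad_fusion:
            raise ConfigError(f"unknown fusion methods: {sorted(bad_fusion)}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigError("train_fraction must lie in (0, 1)")
        if "vote" in self.fusion and len(self.classifiers) < 2:
            raise ConfigError("fusion requires at least 2 classifiers")
        for key in ("cube", "dem", "samples"):
            path = self.inputs.get(key)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"input path does not exist: {path}")


def load_config(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(ExperimentConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = ExperimentConfig(**raw)
    for key in ("classifiers", "fusion", "cmp_thresholds"):
        setattr(cfg, key, tuple(getattr(cfg, key)))
    cfg.validate()
    return cfg


def _scene_config(scene: dict[str, Any], seed: int) -> SceneConfig:
    scene = dict(scene)
    if "shape" in scene:
        scene["shape"] = tuple(scene["shape"])
    if "signatures" in scene:
        scene["signatures"] = {
            name: ClassSignature(**params) for name, params in scene["signatures"].items()
        }
    scene.setdefault("seed", seed)
    return default_scene_config(**scene)


def _stage(manifest: dict, name: str):
    class _StageTimer:
        def __enter__(self):
            log.info("stage %s: start", name)
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                manifest["timings_s"][name] = round(dt, 3)
                log.info("stage %s: done in %.2fs", name, dt)
                return False
            manifest["status"] = "failed"
            manifest["failed_stage"] = name
            log.error("stage %s: FAILED (%s); partial outputs are stale", name, exc)
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    return _StageTimer()


def _load_or_simulate(cfg: ExperimentConfig, seed: int, need_samples: bool = True):
    if cfg.inputs.get("cube"):
        cube = read_cube(cfg.inputs["cube"])
        dem, _ = read_raster(cfg.inputs["dem"])
        truth = None
        scheme = None
        if cfg.inputs.get("truth"):
            truth = read_map(cfg.inputs["truth"])
            scheme = truth.scheme
        samples = None
        if cfg.inputs.get("samples"):
            from .types import default_scheme

            scheme = scheme or default_scheme()
            samples = read_samples(cfg.inputs["samples"], scheme, cube.geotransform)
        return cube, np.asarray(dem, float), truth, samples, scheme
    scfg = _scene_config(cfg.scene, seed)
    cube, dem, truth = simulate_scene(scfg)
    samples = None
    if need_samples:
        samples = sample_reference_points(
            truth, cfg.n_per_class, cfg.homogeneity_window, seed=seed + 1
        )
    return cube, dem, truth, samples, truth.scheme


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path) -> dict:
    """Execute the configured experiment; returns the run manifest."""
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "tool": "lulcfuse",
        "version": __version__,
        "config": asdict(cfg),
        "status": "running",
        "timings_s": {},
        "outputs": {},
        "metrics": {},
    }

    with _stage(manifest, "inputs"):
        cube, dem, truth, samples, scheme = _load_or_simulate(cfg, cfg.seed)
        if samples is None:
            raise ConfigError("no reference samples available")
        if truth is not None:
            write_map(truth, out / "truth.tif")
            manifest["outputs"]["truth"] = "truth.tif"

    with _stage(manifest, "features"):
        feats = assemble_features(
            cube, dem, cfg.combo, points=(samples.rows, samples.cols)
        )
        samples.features = feats

    with _stage(manifest, "split"):
        samples = stratified_split(samples, cfg.train_fraction, seed=cfg.seed + 2)
        train, test = samples.split_part("train"), samples.split_part("test")

    models = {}
    with _stage(manifest, "train"):
        for kind in cfg.classifiers:
            models[kind] = train_backend(
                kind,
                train,
                hyperparams=cfg.hyperparams.get(kind),
                seed=cfg.seed + 3,
                scheme=scheme,
            )

    test_probs: dict[str, np.ndarray] = {}
    codes_arr = np.asarray(scheme.codes)
    with _stage(manifest, "predict"):
        for kind, model in models.items():
            test_probs[kind] = predict_proba(model, test.features, scheme=scheme)
        map_probs: dict[str, ProbabilityCube] = {}
        if cfg.classify_map:
            full_feats = assemble_features(cube, dem, cfg.combo)
            r, c = cube.shape
            for kind, model in models.items():
                p = predict_proba(model, full_feats, scheme=scheme)
                map_probs[kind] = ProbabilityCube(
                    p.T.reshape(scheme.n_classes, r, c),
                    scheme,
                    source=kind,
                    geotransform=cube.geotransform,
                    crs=cube.crs,
                )

    with _stage(manifest, "assess_members"):
        reports = {}
        for kind in cfg.classifiers:
            pred = codes_arr[test_probs[kind].argmax(axis=1)]
            rep = accuracy_report(
                confusion_matrix(pred, test.codes, scheme, include_unclassified=False)
            )
            reports[kind] = rep
            rep.summary().to_csv(out / f"accuracy_{kind}.csv", index=False)
            manifest["metrics"][f"{kind}_oa_pct"] = round(rep.oa, 3)
            manifest["metrics"][f"{kind}_kappa_pct"] = round(rep.kappa, 3)

    with _stage(manifest, "fuse"):
        sample_cubes = [
            ProbabilityCube(test_probs[k].T, scheme, source=k) for k in cfg.classifiers
        ]
        if "bayes" in cfg.fusion:
            fused = fuse_bayesian(sample_cubes)
            pred = fused.fused_map.labels.ravel()
            rep = accuracy_report(
                confusion_matrix(pred, test.codes, scheme, include_unclassified=False)
            )
            rep.summary().to_csv(out / "accuracy_bayes.csv", index=False)
            manifest["metrics"]["bayes_oa_pct"] = round(rep.oa, 3)
            manifest["metrics"]["bayes_kappa_pct"] = round(rep.kappa, 3)
        if "vote" in cfg.fusion:
            member_maps = [
                LULCMap(
                    codes_arr[test_probs[k].argmax(axis=1)][None, :],
                    scheme,
                )
                for k in cfg.classifiers
            ]
            vote = fuse_majority(member_maps)
            pred = vote.fused_map.labels.ravel()
            rep = accuracy_report(
                confusion_matrix(pred, test.codes, scheme, include_unclassified=True)
            )
            rep.summary().to_csv(out / "accuracy_vote.csv", index=False)
            manifest["metrics"]["vote_oa_pct"] = round(rep.oa, 3)
            manifest["metrics"]["vote_kappa_pct"] = round(rep.kappa, 3)

    if cfg.classify_map and map_probs:
        with _stage(manifest, "map_products"):
            from .io import write_probability_cube

            member_label_maps = {}
            for kind, pcube in map_probs.items():
                from .fusion import argmax_label

                lmap, _ = argmax_label(pcube)
                member_label_maps[kind] = lmap
                write_map(lmap, out / f"map_{kind}.tif")
                manifest["outputs"][f"map_{kind}"] = f"map_{kind}.tif"
            if "bayes" in cfg.fusion:
                fused = fuse_bayesian(list(map_probs.values()))
                write_map(fused.fused_map, out / "map_bayes.tif")
                write_probability_cube(fused.fused_probs, out / "probs_bayes.tif")
                write_raster(
                    out / "cmp_bayes.tif",
                    np.where(np.isfinite(fused.cmp), fused.cmp, -1.0).astype(
                        np.float32
                    ),
                    geotransform=cube.geotransform,
                    crs=cube.crs,
                    nodata=-1.0,
                )
                manifest["outputs"]["map_bayes"] = "map_bayes.tif"
                hist = cmp_histogram(fused.cmp[np.isfinite(fused.cmp)])
                hist.to_csv(out / "cmp_histogram.csv", index=False)
                for t in cfg.cmp_thresholds:
                    low = fused.cmp <= t
                    if low.any():
                        tab = proportion_ratio(
                            fused.fused_map.labels[low],
                            fused.fused_map,
                            scheme,
                            flag_threshold=cfg.ratio_flag_threshold,
                        )
                        tab.to_csv(
                            out / f"proportion_ratio_cmp_le_{t:g}.csv", index=False
                        )
                manifest["metrics"]["cmp_frac_above_0.5"] = float(
                    (fused.cmp[np.isfinite(fused.cmp)] > 0.5).mean()
                )
            if "vote" in cfg.fusion:
                vote = fuse_majority(list(member_label_maps.values()))
                write_map(vote.fused_map, out / "map_vote.tif")
                write_raster(
                    out / "votes.tif",
                    vote.vote_map.counts.astype(np.int16),
                    geotransform=cube.geotransform,
                    crs=cube.crs,
                    nodata=-1,
                )
                manifest["outputs"]["map_vote"] = "map_vote.tif"
                counts = vote.vote_map.counts
                valid = counts > 0
                k = len(cfg.classifiers)
                manifest["metrics"]["vote_consensus_frac"] = float(
                    (counts[valid] == k).mean()
                )
                unc = vote.fused_map.labels == scheme.unclassified_code
                if unc.any():
                    for kind, lmap in member_label_maps.items():
                        tab = proportion_ratio(
                            lmap.labels[unc],
                            lmap,
                            scheme,
                            flag_threshold=cfg.ratio_flag_threshold,
                        )
                        tab.to_csv(
                            out / f"proportion_ratio_unclassified_{kind}.csv",
                            index=False,
                        )

    if cfg.sensitivity.get("enabled"):
        with _stage(manifest, "sensitivity"):
            curves = sample_size_sensitivity(
                train.features.values,
                train.codes,
                test.features.values,
                test.codes,
                scheme,
                kinds=tuple(cfg.classifiers),
                fractions=tuple(cfg.sensitivity.get("fractions", (0.1, 0.5, 1.0))),
                replicates=int(cfg.sensitivity.get("replicates", 5)),
                seed=cfg.seed + 4,
                hyperparams=cfg.hyperparams,
            )
            import pandas as pd

            pd.concat([c.to_dataframe() for c in curves.values()]).to_csv(
                out / "sensitivity.csv", index=False
            )

    if cfg.change.get("enabled"):
        with _stage(manifest, "change"):
            second_seed = int(cfg.change.get("second_seed", cfg.seed + 100))
            cube2, dem2, truth2, _, _ = _load_or_simulate(
                cfg, second_seed, need_samples=False
            )
            feats2 = assemble_features(cube2, dem2, cfg.combo)
            r, c = cube2.shape
            probs2 = [
                ProbabilityCube(
                    predict_proba(models[k], feats2, scheme=scheme).T.reshape(
                        scheme.n_classes, r, c
                    ),
                    scheme,
                    source=k,
                    geotransform=cube2.geotransform,
                )
                for k in cfg.classifiers
            ]
            fused2 = fuse_bayesian(probs2)
            map_t2 = fused2.fused_map
            if cfg.classify_map and "bayes" in cfg.fusion:
                map_t1 = read_map(out / "map_bayes.tif")
            else:
                map_t1 = truth if truth is not None else map_t2
            cmat = conversion_matrix(
                map_t1, map_t2, pixel_area_km2=cfg.change.get("pixel_area_km2")
            )
            cmat.to_dataframe().to_csv(out / "conversion_matrix.csv")
            class_area_change(cmat).to_csv(out / "area_change.csv", index=False)
            manifest["outputs"]["conversion_matrix"] = "conversion_matrix.csv"

    manifest["status"] = "ok"
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
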