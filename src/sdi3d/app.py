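"""Orchestration: synthetic fixture generation and batch SDI analyses.

The fixture generator reproduces the package's synthetic benchmark: patterns
of 10 spheres of radius 5 in a spherical domain of radius 30 (all lengths in
voxel units), under the completely random model and under border attraction
(μ=5, σ=5) and border repulsion (μ=15, σ=5), 100 patterns per model.  These
are the conditions used throughout the validation suite.
"""

from __future__ import annotations

import glob
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .errors import Sdi3dError
from .geometry import SphereDomain, rasterize_pattern
from .inference import compare_mean_distances, compute_sdi_multi, test_uniformity
from .models import ModelSpec
from .models import simulate as simulate_model
from .patterns import read_pattern, validate_pattern, write_pattern

logger = logging.getLogger("sdi3d")

__all__ = ["RunConfig", "generate_fixtures", "run_full_analysis",
           "BENCHMARK_RADIUS", "BENCHMARK_N", "BENCHMARK_OBJECT_RADIUS"]

#: synthetic benchmark geometry (voxel units)
BENCHMARK_RADIUS = 30.0
BENCHMARK_N = 10
BENCHMARK_OBJECT_RADIUS = 5.0

_FIXTURE_MODELS = {
    "csr": {},
    "border_attraction": {"mu": 5.0, "sigma": 5.0},
    "border_repulsion": {"mu": 15.0, "sigma": 5.0},
}


@dataclass
class RunConfig:
    """Configuration of a batch run (fixture generation or analysis)."""

    out_dir: str
    seed: int
    input_dir: str | None = None
    models: list = field(default_factory=lambda: ["csr"])
    descriptors: list = field(default_factory=lambda: ["F", "G", "H", "B", "C", "Z"])
    n_patterns: int = 100
    n_sim1: int = 99
    n_sim2: int = 99
    n_positions: int = 10_000
    with_masks: bool = False
    mask_spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.seed is None:
            raise Sdi3dError("a seed is mandatory for stochastic runs")


def _write_manifest(path: str, payload: dict) -> None:
    payload = dict(payload)
    payload["sdi3d_version"] = __version__
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")


def generate_fixtures(config: RunConfig) -> dict:
    """Write the synthetic benchmark fixture set to ``config.out_dir``.

    One subdirectory per model with ``pattern_###.csv`` files (plus JSON
    sidecars); optional rasterized TIFF mask/label stacks; a manifest echoing
    the full configuration.  Byte-identical across runs with the same seed.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    domain = SphereDomain(BENCHMARK_RADIUS, center=(BENCHMARK_RADIUS,) * 3)
    radii = np.full(BENCHMARK_N, BENCHMARK_OBJECT_RADIUS)
    rng = np.random.default_rng(config.seed)
    written = {}
    for model, params in _FIXTURE_MODELS.items():
        spec = ModelSpec(model, radii=radii, **params)
        sub = os.path.join(config.out_dir, model)
        os.makedirs(sub, exist_ok=True)
        files = []
        for k in range(config.n_patterns):
            pat = simulate_model(domain, spec, rng)
            path = os.path.join(sub, f"pattern_{k:03d}.csv")
            write_pattern(pat, path)
            files.append(path)
            if config.with_masks:
                import tifffile

                mask, labels, origin = rasterize_pattern(pat, config.mask_spacing)
                tifffile.imwrite(os.path.join(sub, f"pattern_{k:03d}_mask.tif"),
                                 mask.astype(np.uint8))
                tifffile.imwrite(os.path.join(sub, f"pattern_{k:03d}_labels.tif"),
                                 labels.astype(np.int32))
            logger.info("fixtures: %s pattern %d/%d", model, k + 1, config.n_patterns)
        written[model] = files
    _write_manifest(os.path.join(config.out_dir, "manifest.json"), {
        "config": asdict(config),
        "domain": domain.to_dict(),
        "models": _FIXTURE_MODELS,
        "n_per_model": config.n_patterns,
    })
    return written


def _load_patterns(input_dir: str):
    paths = sorted(glob.glob(os.path.join(input_dir, "pattern_*.csv")))
    if not paths:
        raise Sdi3dError(f"no pattern CSV files found in {input_dir}")
    return [read_pattern(p) for p in paths], paths


def run_full_analysis(config: RunConfig) -> pd.DataFrame:
    """SDI-test a directory of patterns against one or more models.

    For each requested (model, descriptor): per-pattern SDI JSON records, a
    population KS table, SDI histogram counts and a matched mean-distance
    comparison.  Deterministic given the seed.
    """
    patterns, paths = _load_patterns(config.input_dir)
    os.makedirs(config.out_dir, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    rows, failures = [], []
    for model in config.models:
        params = _FIXTURE_MODELS.get(model, {})
        spec = ModelSpec(model, radii=np.ones(1), **params)
        if model.startswith("orbital"):
            spec = ModelSpec(model, radii=np.ones(1), orbit_distances=np.ones(1))
        sdis = {d: [] for d in config.descriptors}
        records = []
        for pat, path in zip(patterns, paths):
            try:
                res = compute_sdi_multi(pat, spec, config.descriptors,
                                        config.n_sim1, config.n_sim2, rng=rng)
            except Sdi3dError as exc:
                logger.warning("skipping %s under %s: %s", path, model, exc)
                failures.append((path, model, str(exc)))
                continue
            rec = {"pattern": os.path.basename(path), "model": model}
            for d, r in res.items():
                sdis[d].append(r.sdi)
                rec[f"sdi_{d}"] = r.sdi
                rec[f"S_{d}"] = r.S
                rec[f"x_star_{d}"] = r.x_star
            records.append(rec)
        with open(os.path.join(config.out_dir, f"sdi_{model}.json"), "w") as fh:
            json.dump(records, fh, indent=1, sort_keys=True)
            fh.write("\n")
        for d in config.descriptors:
            if len(sdis[d]) >= 10:
                t = test_uniformity(sdis[d], descriptor=d, model=model)
                rows.append({"model": model, "descriptor": d, "n": t.n,
                             "ks_statistic": t.statistic, "p_value": t.p_value})
        hist = {d: np.histogram(sdis[d], bins=10, range=(0, 1))[0].tolist()
                for d in config.descriptors if sdis[d]}
        with open(os.path.join(config.out_dir, f"sdi_hist_{model}.json"), "w") as fh:
            json.dump(hist, fh, indent=1, sort_keys=True)
            fh.write("\n")
        try:
            cmp_res = compare_mean_distances(patterns, spec, "nearest",
                                             n_sim_per_pattern=9, rng=rng)
            pd.DataFrame({"pattern": [os.path.basename(p) for p in paths],
                          "observed_mean_nn": cmp_res.observed,
                          "model_mean_nn": cmp_res.predicted}).to_csv(
                os.path.join(config.out_dir, f"mean_nn_{model}.csv"),
                index=False, float_format="%.12g")
            rows.append({"model": model, "descriptor": "mean_nn_wilcoxon",
                         "n": len(patterns), "ks_statistic": cmp_res.statistic,
                         "p_value": cmp_res.p_value})
        except Sdi3dError as exc:
            logger.warning("mean-distance comparison skipped for %s: %s", model, exc)
    table = pd.DataFrame(rows)
    table.to_csv(os.path.join(config.out_dir, "population_tests.csv"),
                 index=False, float_format="%.12g")
    _write_manifest(os.path.join(config.out_dir, "manifest.json"), {
        "config": asdict(config), "n_patterns": len(patterns),
        "failures": failures,
    })
    if failures:
        logger.warning("%d pattern/model combinations failed", len(failures))
    return table
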