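"""End-to-end orchestration: simulate/load -> predict -> interpret.

A run is driven by a single config (YAML/JSON/dict), executes the staged
analysis, and leaves a run directory whose manifest (package versions,
seeds, config echo, input hashes) is sufficient to reproduce every number
in the report.  Seeds are mandatory wherever randomness enters; a missing
seed is an error, never a silent default.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import io as mio
from .interpretation import (
    aggregate_weights,
    module_pair_summary,
    report_to_frame,
    select_top_edges,
)
from .prediction import (
    loocv_predict,
    permutation_test,
    repeated_kfold_predict,
)
from .rvr import RVRFitConfig, fit as rvr_fit, primal_weights
from .synthetic import CovariateSpec, ExtraFeature, SimulationConfig, simulate_cohort

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("memconn")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input source: either ``simulate`` (a SimulationConfig or
    its dict form) or the triple of ``features_path`` / ``subjects_path``
    / ``atlas_path``.
    """

    out_dir: str
    target: str = "avlt_dr"
    covariates: tuple[str, ...] = ("age", "sex", "education")
    scheme: str = "loocv"              # or "kfold"
    k: int = 10
    repeats: int = 100
    n_perm: int = 1000
    fraction: float = 0.01
    seed: int | None = None
    simulate: SimulationConfig | None = None
    features_path: str | None = None
    subjects_path: str | None = None
    atlas_path: str | None = None
    weight_source: str = "folds"       # or "refit": full-data model weights
    rvr: RVRFitConfig = field(default_factory=RVRFitConfig)

    def __post_init__(self) -> None:
        file_mode = self.features_path is not None
        if file_mode == (self.simulate is not None):
            raise ValueError(
                "exactly one input source required: 'simulate' or file paths"
            )
        if file_mode and (self.subjects_path is None or self.atlas_path is None):
            raise ValueError("file input needs features_path, subjects_path and atlas_path")
        if self.scheme not in ("loocv", "kfold"):
            raise ValueError("scheme must be 'loocv' or 'kfold'")
        if self.weight_source not in ("folds", "refit"):
            raise ValueError("weight_source must be 'folds' or 'refit'")
        if self.seed is None:
            raise ValueError("seed is required")
        if isinstance(self.simulate, dict):
            sim = dict(self.simulate)
            if isinstance(sim.get("covariates"), dict):
                sim["covariates"] = CovariateSpec(**sim["covariates"])
            if sim.get("extra_features"):
                sim["extra_features"] = tuple(
                    ExtraFeature(**e) if isinstance(e, dict) else e
                    for e in sim["extra_features"]
                )
            if sim.get("signal_edges"):
                sim["signal_edges"] = tuple(tuple(e) for e in sim["signal_edges"])
            self.simulate = SimulationConfig(**sim)
        if isinstance(self.rvr, dict):
            self.rvr = RVRFitConfig(**self.rvr)
        self.covariates = tuple(self.covariates)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # re-tag with the failing stage
                raise PipelineError(f"[{name}] {exc}") from exc
            log.info("stage %s: done in %.1f s", name, time.time() - t0)
            return out
        return wrapper
    return deco


@_stage("input")
def _load_inputs(config: RunConfig, out: Path):
    if config.simulate is not None:
        cohort = simulate_cohort(config.simulate)
        atlas = cohort.atlas
        table = cohort.subject_table
        X = cohort.features(extra=bool(cohort.truth.get("extra_feature_names")))
        mio.write_atlas(atlas, out / "atlas.tsv")
        mio.write_subject_table(table, out / "subjects.csv")
        mio.write_feature_matrix(
            X, out / "features.csv", atlas.n_nodes,
            table["subject_id"],
            extra_names=cohort.truth.get("extra_feature_names", []),
        )
        mio.write_truth(cohort.truth, out / "truth.json")
        hashes = {}
    else:
        atlas = mio.read_atlas(config.atlas_path)
        required = (config.target, *config.covariates)
        table = mio.read_subject_table(config.subjects_path, required=required)
        X, ids, _ = mio.read_feature_matrix(config.features_path)
        if list(table["subject_id"].astype(str)) != ids:
            raise ValueError("subject order differs between table and feature matrix")
        hashes = {
            str(p): _sha256(p)
            for p in (config.features_path, config.subjects_path, config.atlas_path)
        }
    if config.target not in table.columns:
        raise ValueError(f"target column '{config.target}' not in subject table")
    for c in config.covariates:
        if c not in table.columns:
            raise ValueError(f"covariate column '{c}' not in subject table")
    return atlas, table, X, hashes


@_stage("predict")
def _predict(config: RunConfig, X, y, C):
    if config.scheme == "loocv":
        cv = loocv_predict(X, y, rvr_config=config.rvr, covariates=C)
    else:
        cv = repeated_kfold_predict(
            X, y, k=config.k, repeats=config.repeats,
            seed=config.seed, rvr_config=config.rvr, covariates=C,
        )
    perm = permutation_test(
        X, y, covariates=C, scheme=config.scheme, n_perm=config.n_perm,
        seed=config.seed, rvr_config=config.rvr, k=config.k,
        repeats=1 if config.scheme == "loocv" else config.repeats,
    )
    return cv, perm


@_stage("interpret")
def _interpret(config: RunConfig, cv, X, y, atlas, n_edge_features: int):
    if config.weight_source == "refit" or cv.models is None:
        from .prediction import apply_scaling, fit_scaling

        scaling = fit_scaling(X)
        model = rvr_fit(apply_scaling(scaling, X), y, config.rvr)
        weights = [primal_weights(model)]
    else:
        weights = cv.models
    mean_w, mean_abs_w = aggregate_weights(weights)
    # extra scalar features sit after the edge block and are not edges
    mean_w, mean_abs_w = mean_w[:n_edge_features], mean_abs_w[:n_edge_features]
    report = select_top_edges(mean_w, mean_abs_w, atlas, config.fraction)
    return report, module_pair_summary(report, atlas)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured analysis; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        log.addHandler(logging.StreamHandler(sys.stderr))
    try:
        atlas, table, X, hashes = _load_inputs(config, out)
        y = table[config.target].to_numpy(dtype=float)
        C = (
            table[list(config.covariates)].to_numpy(dtype=float)
            if config.covariates
            else None
        )
        cv, perm = _predict(config, X, y, C)
        n_edge_features = atlas.n_nodes * (atlas.n_nodes - 1) // 2
        report, pair_table = _interpret(config, cv, X, y, atlas, n_edge_features)
    except PipelineError:
        log.removeHandler(handler)
        handler.close()
        raise
    except Exception as exc:
        log.removeHandler(handler)
        handler.close()
        raise PipelineError(f"[run] {exc}") from exc

    try:
        preds = table[["subject_id"]].copy()
        preds["actual"] = y
        preds["predicted"] = cv.predictions
        preds.to_csv(out / "predictions.csv", index=False)
        mio.write_json(cv.to_dict(), out / "cv_result.json")
        mio.write_json(perm.to_dict(), out / "permutation.json")
        mio.write_json(report.to_dict(), out / "report.json")
        report_to_frame(report, atlas).to_csv(out / "top_edges.csv", index=False)
        pair_table.to_csv(out / "module_pairs.csv", index=False)
        mio.write_brainnet_node(atlas, out / "atlas.node")
        mio.write_brainnet_edge(report, atlas, out / "selected.edge")
        manifest = {
            "memconn_version": __version__,
            "numpy_version": np.__version__,
            "seed": config.seed,
            "config": _config_echo(config),
            "input_hashes": hashes,
        }
        mio.write_json(manifest, out / "manifest.json")
    finally:
        log.removeHandler(handler)
        handler.close()
    return out


def _config_echo(config: RunConfig) -> dict:
    def enc(obj):
        if hasattr(obj, "__dataclass_fields__"):
            return {k: enc(getattr(obj, k)) for k in obj.__dataclass_fields__}
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    return enc(config)
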