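"""End-to-end pipeline: preprocess -> rank selection -> decompose -> predict.

Configuration is a YAML/dict description of the input blocks (paths and
assay kinds), covariate/outcome table, per-block filter specs, rank
overrides, decomposition options and prediction options. Every stage writes
its outputs as TSV under the output directory, and a JSON run manifest
records the config snapshot, per-stage seeds, selected ranks, thresholds
and wall times, so a rerun with the same config and seeds reproduces the
deterministic outputs bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ajive import AjiveResult, ajive
from .blocks import (
    MultiOmicsCollection,
    OmicsBlock,
    align_samples,
    read_block,
    read_sample_table,
    write_block,
)
from .predict import (
    build_covariate_features,
    build_integrative_features,
    build_pca_features,
    cv_auc,
    lasso_protocol,
    random_forest_eval,
)
from .preprocess import FilterSpec, preprocess_counts, preprocess_methylation, svdmiss_impute, center_features
from .ranks import select_initial_ranks

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``load_config`` for the schema)."""

    blocks: list[dict]  # each: {name, path, assay_kind, filter: {...}}
    sample_table: str | None  # TSV with covariate columns + outcome column
    covariate_columns: list[str] = field(default_factory=lambda: ["age", "bmi", "smoking"])
    outcome_column: str = "outcome"
    outcome_kind: str = "binary"
    rank_overrides: dict[str, int] = field(default_factory=dict)
    max_rank_frac: float = 0.5
    decomposition: dict = field(default_factory=dict)  # ajive() keyword options
    prediction: dict = field(default_factory=dict)  # n_individual, n_pcs, k, repeats...
    out_dir: str = "ajive_run"
    seed: int = 0

    def __post_init__(self) -> None:
        for b in self.blocks:
            if "path" not in b or "assay_kind" not in b:
                raise ValueError("every block needs 'path' and 'assay_kind'")
            b.setdefault("name", Path(b["path"]).stem)
            b.setdefault("filter", {})
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    config: dict
    package_version: str
    stages: list[dict] = field(default_factory=list)
    output_checksums: dict[str, str] = field(default_factory=dict)

    def add_stage(self, name: str, seconds: float, **info) -> None:
        self.stages.append({"stage": name, "wall_seconds": round(seconds, 3), **info})

    def write(self, path: Path) -> None:
        payload = {
            "package_version": self.package_version,
            "config": self.config,
            "stages": self.stages,
            "output_checksums": self.output_checksums,
        }
        path.write_text(json.dumps(payload, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return PipelineConfig(**raw)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _preprocess_block(block: OmicsBlock, spec_dict: dict) -> OmicsBlock:
    spec = FilterSpec(**{k: v for k, v in spec_dict.items() if k != "skip"})
    if spec_dict.get("skip"):
        return center_features(svdmiss_impute(block) if block.has_missing else block)
    if block.assay_kind in ("methylation_beta", "methylation_m"):
        out, _ = preprocess_methylation(block, spec)
        return out
    if block.assay_kind == "counts":
        out, _ = preprocess_counts(block, spec)
        return out
    # expression paths: optional variance filter, impute, center
    from .preprocess import variance_filter

    if spec.top_n_variance is not None and spec.top_n_variance < block.n_features:
        block, _ = variance_filter(block, spec.top_n_variance)
    if block.has_missing:
        block = svdmiss_impute(block)
    return center_features(block)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis described by ``config``.

    Stage order: read+align -> per-block preprocessing -> profile-likelihood
    rank selection -> aJIVE decomposition -> prediction models (integrative,
    per-block-PCA comparator, covariates-only, lasso, random forest).
    Failures abort with the stage name; outputs written so far persist.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=json.loads(json.dumps(config.__dict__, default=_jsonable)),
        package_version=__version__,
    )
    manifest_path = out_dir / "manifest.json"

    def fail(stage: str, exc: Exception):
        manifest.add_stage(stage, 0.0, error=str(exc))
        manifest.write(manifest_path)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- read + align ------------------------------------------------------
    t0 = time.perf_counter()
    try:
        blocks = [
            read_block(b["path"], b["assay_kind"], name=b["name"]) for b in config.blocks
        ]
        covariates = outcome = None
        if config.sample_table:
            table = read_sample_table(config.sample_table)
            covariates = table[config.covariate_columns]
            outcome = table[config.outcome_column]
        collection = align_samples(blocks, covariates, outcome)
    except Exception as exc:
        fail("read_align", exc)
    manifest.add_stage(
        "read_align",
        time.perf_counter() - t0,
        n_samples=collection.n_samples,
        block_dims=[b.n_features for b in collection.blocks],
    )

    # --- preprocess --------------------------------------------------------
    t0 = time.perf_counter()
    try:
        processed = [
            _preprocess_block(b, cfg["filter"])
            for b, cfg in zip(collection.blocks, config.blocks)
        ]
        collection = MultiOmicsCollection(
            blocks=processed, covariates=collection.covariates, outcome=collection.outcome
        )
        for b in processed:
            write_block(b, out_dir / f"preprocessed_{b.name}.tsv")
    except Exception as exc:
        fail("preprocess", exc)
    manifest.add_stage(
        "preprocess",
        time.perf_counter() - t0,
        block_dims=[b.n_features for b in collection.blocks],
    )

    # --- rank selection ----------------------------------------------------
    t0 = time.perf_counter()
    try:
        ranksel = select_initial_ranks(
            collection, max_rank_frac=config.max_rank_frac, overrides=config.rank_overrides
        )
        pd.DataFrame(
            {"block": ranksel.block_names, "initial_rank": ranksel.initial_ranks}
        ).to_csv(out_dir / "initial_ranks.tsv", sep="\t", index=False)
    except Exception as exc:
        fail("rank_selection", exc)
    manifest.add_stage(
        "rank_selection", time.perf_counter() - t0, initial_ranks=ranksel.initial_ranks
    )

    # --- decomposition -----------------------------------------------------
    t0 = time.perf_counter()
    try:
        opts = dict(config.decomposition)
        opts.setdefault("seed", config.seed)
        result = ajive(collection, initial_ranks=ranksel, **opts)
        write_decomposition(result, collection, out_dir)
    except Exception as exc:
        fail("decompose", exc)
    manifest.add_stage(
        "decompose",
        time.perf_counter() - t0,
        joint_rank=result.joint_rank,
        individual_ranks=result.individual_ranks,
        wedin_threshold=result.joint.wedin_threshold,
        random_threshold=result.joint.random_threshold,
        seed=opts["seed"],
    )

    # --- prediction --------------------------------------------------------
    t0 = time.perf_counter()
    try:
        reports = run_prediction_suite(result, collection, config)
        summary = pd.DataFrame(
            [
                {
                    "model": name,
                    "kind": rep.model_kind,
                    "mean_auc": rep.mean_auc,
                    "accuracy": rep.accuracy,
                    "oob_error_pct": rep.oob_error_pct,
                }
                for name, rep in reports.items()
            ]
        )
        summary.to_csv(out_dir / "prediction_summary.tsv", sep="\t", index=False)
    except Exception as exc:
        fail("predict", exc)
    manifest.add_stage(
        "predict",
        time.perf_counter() - t0,
        seed=config.seed,
        mean_aucs={name: rep.mean_auc for name, rep in reports.items()},
    )

    for f in sorted(out_dir.glob("*.tsv")):
        manifest.output_checksums[f.name] = _checksum(f)
    manifest.write(manifest_path)
    return manifest


def write_decomposition(result: AjiveResult, collection: MultiOmicsCollection, out_dir: Path) -> None:
    """Write J/I/E matrices, scores, loadings and the summary as TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = collection.sample_ids
    pd.DataFrame(
        result.joint.joint_basis,
        index=samples,
        columns=[f"Joint_{i + 1}" for i in range(result.joint_rank)],
    ).to_csv(out_dir / "joint_scores.tsv", sep="\t", index_label="sample_id")
    for b, orig in zip(result.blocks, collection.blocks):
        for part, mat in (("J", b.joint), ("I", b.individual), ("E", b.residual)):
            pd.DataFrame(mat, index=orig.feature_ids, columns=samples).to_csv(
                out_dir / f"{b.name}_{part}.tsv", sep="\t", index_label="feature_id"
            )
        pd.DataFrame(
            b.individual_scores,
            index=samples,
            columns=[f"{b.name}Ind_{i + 1}" for i in range(b.individual_rank)],
        ).to_csv(out_dir / f"{b.name}_individual_scores.tsv", sep="\t", index_label="sample_id")
    result.variance_explained.to_csv(
        out_dir / "variance_explained.tsv", sep="\t", index_label="block"
    )
    summary = {
        "joint_rank": result.joint_rank,
        "individual_ranks": result.individual_ranks,
        "initial_ranks": result.provenance.get("initial_ranks"),
        "wedin_threshold": result.joint.wedin_threshold,
        "random_threshold": result.joint.random_threshold,
        "squared_singular_values": result.joint.squared_singular_values[:10],
    }
    (out_dir / "decomposition_summary.json").write_text(
        json.dumps(summary, indent=2, default=_jsonable)
    )


def run_prediction_suite(
    result: AjiveResult, collection: MultiOmicsCollection, config: PipelineConfig
) -> dict:
    """Fit the integrative, comparator and baseline models of the protocol."""
    pred = dict(config.prediction)
    n_individual = pred.get("n_individual", 5)
    n_pcs = pred.get("n_pcs", 5)
    k = pred.get("k", 10)
    repeats = pred.get("lasso_repeats", 50)
    n_trees = pred.get("n_trees", 1000)
    seed = config.seed
    model_kind = "multinomial" if config.outcome_kind == "categorical4" else "logistic"

    covs, y = collection.covariates, collection.outcome
    integrative = build_integrative_features(result, covs, y, n_individual=n_individual)
    pca = build_pca_features(collection.blocks, covs, y, n_pcs=n_pcs)
    cov_only = build_covariate_features(covs, y)

    reports = {
        "integrative": cv_auc(integrative, model_kind, k=k, seed=seed),
        "non_integrative_pca": cv_auc(pca, model_kind, k=k, seed=seed),
        "covariates_only": cv_auc(cov_only, model_kind, k=k, seed=seed),
        "random_forest_integrative": random_forest_eval(
            integrative, n_trees=n_trees, seed=seed
        ),
        "random_forest_pca": random_forest_eval(pca, n_trees=n_trees, seed=seed),
    }
    if model_kind == "logistic" and repeats > 0:
        reports["lasso"] = lasso_protocol(
            collection.blocks, covs, y, repeats=repeats, seed=seed
        )
    return reports
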