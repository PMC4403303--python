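"""One-command end-to-end pipeline: preprocess -> train (per feature
level) -> similarity -> reports -> GLM reduction analysis.

All randomness funnels through one root seed; a manifest records the
configuration hash, derived seeds, package version, and every file the
run produced, so reruns with identical config and seed are reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

import toxitopic
from toxitopic import analysis, att, glm, preprocess

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run (YAML-loadable)."""

    expr_path: str
    meta_path: str
    out_dir: str
    gmt_path: str | None = None
    # preprocessing
    deg_threshold: float = 1.5
    count_scale: float = 1.0
    signed_tokens: bool = False
    levels: list[str] = field(default_factory=lambda: ["treatment", "drug", "time_dose"])
    # model; K per feature level
    K: dict[str, int] = field(
        default_factory=lambda: {"treatment": 200, "drug": 100, "time_dose": 100}
    )
    iterations: int = 3000
    burn_in: int = 200
    optimize_interval: int = 10
    alpha0: float = 50.0
    beta0: float = 0.01
    seed: int = 7
    # analysis / glm
    top_n: int = 10
    glm_family: str = "gaussian"
    glm_scopes: list[str] = field(default_factory=list)

    def validate(self) -> None:
        for name, p in (("expr_path", self.expr_path), ("meta_path", self.meta_path)):
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} does not exist: {p}")
        if self.gmt_path and not Path(self.gmt_path).exists():
            raise FileNotFoundError(f"gmt_path does not exist: {self.gmt_path}")
        if self.deg_threshold < 1:
            raise ValueError("deg_threshold must be >= 1")
        for level in self.levels:
            if level not in ("treatment", "drug", "time_dose"):
                raise ValueError(f"unknown feature level {level!r}")
            if self.K.get(level, 0) < 1:
                raise ValueError(f"K for level {level!r} must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and write a manifest; returns the run directory.

    Any stage error aborts the run with the stage named; partial outputs
    are retained under a ``FAILED`` marker file.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": toxitopic.__version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "defaults_used": {
            "deg_threshold": config.deg_threshold,
            "count_scale": config.count_scale,
            "glm_family": config.glm_family,
            "skl_log_base": "e (nats)",
            "replicate_mean": "arithmetic",
        },
        "outputs": [],
        "stages": [],
    }
    seeds = np.random.SeedSequence(config.seed).generate_state(len(config.levels) + 1)
    seeds = [int(s % (2**31 - 1)) for s in seeds]

    def record(path: Path) -> None:
        manifest["outputs"].append(str(path.relative_to(out)))

    stage = "load"
    try:
        study = preprocess.load_study(config.expr_path, config.meta_path)

        stage = "preprocess"
        fc = preprocess.compute_fold_changes(study)
        fc = preprocess.apply_deg_filter(fc, threshold=config.deg_threshold)
        fc.to_tsv(out / "fold_changes.tsv")
        record(out / "fold_changes.tsv")
        base_corpus = preprocess.discretize_to_counts(
            fc, scale=config.count_scale, signed_tokens=config.signed_tokens
        )

        for level, level_seed in zip(config.levels, seeds):
            stage = f"train[{level}]"
            corpus = preprocess.regroup_by_feature(base_corpus, level)
            corpus_dir = corpus.save(out / f"corpus_{level}")
            for f in corpus_dir.iterdir():
                record(f)
            model = att.train(
                corpus,
                K=config.K[level],
                iterations=config.iterations,
                burn_in=config.burn_in,
                optimize_interval=config.optimize_interval,
                alpha0=config.alpha0,
                beta0=config.beta0,
                seed=level_seed,
            )
            model_dir = model.save(out / f"model_{level}")
            for f in model_dir.iterdir():
                record(f)
            manifest["stages"].append({"stage": stage, "seed": level_seed, "K": config.K[level]})

            stage = f"similarity[{level}]"
            sim = analysis.pairwise_skl(model.theta, model.author_ids)
            sim.to_tsv(out / f"skl_{level}.tsv")
            record(out / f"skl_{level}.tsv")

            stage = f"reports[{level}]"
            lists_dir = analysis.export_gene_lists(model, out / f"gene_lists_{level}")
            for f in lists_dir.iterdir():
                record(f)

            if level == "treatment" and config.glm_scopes:
                stage = "glm"
                report = glm.reduction_report(sim, config.glm_scopes, family=config.glm_family)
                report.to_csv(out / "glm_reduction.tsv", sep="\t", index=False)
                record(out / "glm_reduction.tsv")
            if level == "time_dose":
                stage = "glm[time_dose]"
                report = glm.reduction_report(sim, ["time_dose_model"], family=config.glm_family)
                report.to_csv(out / "glm_time_dose.tsv", sep="\t", index=False)
                record(out / "glm_time_dose.tsv")

        manifest_path = out / "manifest.json"
        manifest["outputs"].append("manifest.json")
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        logger.info("pipeline finished: %s", out)
        return out
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
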