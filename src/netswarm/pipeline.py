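"""End-to-end pipeline: read → prefilter → infer → rank → export.

Configuration is a single schema readable from YAML or JSON. Every run writes
its outputs plus a ``manifest.json`` recording the configuration, all derived
seeds (and the rule deriving the per-model seeds), and SHA-256 checksums of
every output file, so that an identical configuration provably reproduces a
run bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import io as nio
from .errors import ConfigError, NetswarmError, PipelineStageError
from .mlp import TrainConfig
from .rank import score_genes, strongest_edges, top_k, write_scores_csv
from .swarm import infer_influence, make_resample_plan

__all__ = [
    "PipelineConfig",
    "TrainBlock",
    "ResamplingBlock",
    "PrefilterBlock",
    "RankingBlock",
    "load_config",
    "run_pipeline",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TrainBlock(_Strict):
    n_hidden: int = Field(2, ge=1)
    learning_rate: float = Field(0.05, gt=0)
    momentum: float = Field(0.9, ge=0, lt=1)
    l2_penalty: float = Field(1e-3, ge=0)
    max_epochs: int = Field(400, ge=1)
    patience: int = Field(30, ge=1)
    init_scale: float = Field(0.5, ge=0)
    activation: str = Field("tanh", pattern="^(tanh|linear)$")
    early_stopping: bool = True

    def to_train_config(self, seed: int) -> TrainConfig:
        return TrainConfig(seed=seed, **self.model_dump())


class ResamplingBlock(_Strict):
    n_resamples: int = Field(25, ge=1)
    train_fraction: float = Field(0.8, gt=0, lt=1)


class PrefilterBlock(_Strict):
    method: str = Field("welch", pattern="^(variance|welch)$")
    n_keep: int | None = Field(None, ge=3)  # None disables the prefilter


class RankingBlock(_Strict):
    k: int = Field(200, ge=1)
    n_edges: int = Field(200, ge=0)
    min_consistency: float = Field(0.0, ge=0, le=1)


class PipelineConfig(_Strict):
    """Full pipeline configuration (unknown keys are rejected)."""

    expression_path: str
    groups_path: str
    output_dir: str
    min_transcripts: int = Field(nio.DEFAULT_MIN_TRANSCRIPTS, ge=1)
    seed: int = 0
    train: TrainBlock = TrainBlock()
    resampling: ResamplingBlock = ResamplingBlock()
    prefilter: PrefilterBlock = PrefilterBlock()
    ranking: RankingBlock = RankingBlock()


def load_config(path) -> PipelineConfig:
    """Load a YAML or JSON configuration file into a validated config."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as err:
        first = err.errors()[0]
        key = ".".join(str(p) for p in first["loc"]) or "<root>"
        raise ConfigError(f"invalid configuration key {key!r}: {first['msg']}") from err


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline and return the run directory.

    Stages: read (with inclusion filter) → optional differential-expression
    prefilter → swarm influence inference → gene scoring and edge ranking →
    interactome/score export → manifest. Any stage failure is re-raised as a
    :class:`PipelineStageError` naming the stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        try:
            return fn()
        except NetswarmError as err:
            raise PipelineStageError(f"stage {name!r} failed: {err}") from err

    dataset = stage("read", lambda: nio.read_expression_matrix(
        config.expression_path, config.groups_path, config.min_transcripts
    ))
    if config.prefilter.n_keep is not None:
        dataset = stage("prefilter", lambda: nio.prefilter_genes(
            dataset, config.prefilter.method, config.prefilter.n_keep
        ))

    plan_seed = config.seed
    train_seed = config.seed
    plan = stage("resample", lambda: make_resample_plan(
        dataset.n_samples,
        config.resampling.n_resamples,
        config.resampling.train_fraction,
        seed=plan_seed,
    ))
    result = stage("infer", lambda: infer_influence(
        dataset, config.train.to_train_config(train_seed), plan
    ))
    scores = stage("rank", lambda: score_genes(result))
    edges = stage("rank", lambda: strongest_edges(
        result, config.ranking.n_edges, config.ranking.min_consistency
    ))

    def export():
        result.save(str(out / "influence"))
        write_scores_csv(scores, out / "scores.csv")
        paths = nio.write_interactome(edges, scores, out / "interactome")
        for role in ("driver", "target"):
            (out / f"top_{role}s.txt").write_text(
                "\n".join(top_k(scores, config.ranking.k, role)) + "\n", encoding="utf-8"
            )
        return paths

    stage("export", export)

    outputs = sorted(
        p for p in out.iterdir()
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": config.model_dump(),
        "seeds": {
            "global": config.seed,
            "resample_plan": plan_seed,
            "train_base": train_seed,
            "per_model_rule": (
                "W_in row ~ SeedSequence(train_base, spawn_key=(resample, "
                "crc32(output_gene), 1 + crc32(input_gene))); "
                "W_out ~ SeedSequence(train_base, spawn_key=(resample, crc32(output_gene), 0))"
            ),
        },
        "n_genes_analyzed": dataset.n_genes,
        "n_samples": dataset.n_samples,
        "checksums": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return out
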