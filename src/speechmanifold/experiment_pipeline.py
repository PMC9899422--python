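"""Factorial experiment orchestration: condition x seed, analysis, reports.

One experiment trains matched network populations on a clean and a degraded
copy of the same dataset (the degraded arm is the clean arm plus frozen
additive Gaussian noise — nothing else differs, by construction and by an
explicit audit), then measures:

* per-epoch training error (learning-curve table),
* test-set accuracy and predictive uncertainty (entropy / max probability,
  over correct responses and over all responses),
* representation geometry — mean-field capacity, dimension, radius —
  epoch-wise at the final convolutional layer and, post-training, across
  every layer in the registry.

Results are a tidy table (condition, seed, epoch, layer, metric, value, se)
from which ``write_report`` derives the learning-curve, uncertainty,
epoch-geometry and layer-geometry CSVs plus a JSON summary and a run
manifest.  Every cell's randomness derives from (base_seed, replicate)
through named SeedSequence children, so the two arms share data seeds and
re-running a cell reproduces its outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import audio_frontend, cnn_model, manifold_geometry, prediction_metrics
from .audio_frontend import FrontendConfig, NoiseConfig
from .cnn_model import ModelConfig, TrainingConfig
from .errors import ConfigurationError, InvalidInputError
from .synthetic_speech import VariationParams, generate_dataset

__all__ = [
    "DataConfig",
    "GeometryConfig",
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
    "write_report",
    "config_to_dict",
    "config_from_dict",
]

logger = logging.getLogger("speechmanifold")

REPORT_FILES = (
    "fig3a_training_error.csv",
    "fig3bc_uncertainty.csv",
    "fig4_epoch_geometry.csv",
    "fig5_layer_geometry.csv",
    "summary.json",
)


@dataclass(frozen=True)
class DataConfig:
    source: str = "synthetic"  # {"synthetic", "wav_directory"}
    wav_root: str | None = None
    n_classes: int = 8
    exemplars_per_class: int = 100
    n_bands: int = 64
    n_frames: int = 32
    train_fraction: float = 0.8
    variation: VariationParams = field(default_factory=VariationParams)
    frontend: FrontendConfig = field(default_factory=FrontendConfig)  # wav source only


@dataclass(frozen=True)
class GeometryConfig:
    """Desk-scale geometry defaults; matched to the default 8-class dataset
    (20 test exemplars per class) and to single-CPU runtimes.  The analysis
    itself is intrinsic to each manifold's subspace, so the projection width
    mainly sets the cost of the orthonormalization."""

    m_exemplars: int = 20
    n_proj: int = 500
    n_gaussian_samples: int = 150
    kappa: float = 0.0
    n_dichotomies: int = 200
    epoch_geometry: bool = True


@dataclass(frozen=True)
class ExperimentConfig:
    data: DataConfig = field(default_factory=DataConfig)
    noise_sd_multiplier: float = 0.1
    model_architecture: str = "tinyconv"
    # lr 0.002: plain SGD at the conventional 0.01 is unstable on this
    # standardized-spectrogram task (mid-training divergence); 0.002 learns
    # smoothly over the 10-epoch budget.
    training: TrainingConfig = field(
        default_factory=lambda: TrainingConfig(learning_rate=0.002)
    )
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    n_seeds: int = 3
    conditions: tuple[str, ...] = ("clean", "degraded")
    base_seed: int = 0

    def __post_init__(self):
        if self.n_seeds < 1:
            raise ConfigurationError("n_seeds must be >= 1")
        for c in self.conditions:
            if c not in ("clean", "degraded"):
                raise ConfigurationError(f"unknown condition {c!r}")


@dataclass
class ExperimentResult:
    table: pd.DataFrame  # tidy: condition, seed, epoch, layer, metric, value, se
    config: ExperimentConfig
    seeds: dict  # replicate -> named seed map
    cell_errors: list[dict] = field(default_factory=list)


def config_to_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    if "conditions" in d:
        d["conditions"] = list(d["conditions"])  # canonical JSON-stable form
    return d


def config_from_dict(d: dict) -> ExperimentConfig:
    d = dict(d)
    data = dict(d.pop("data", {}))
    variation = VariationParams(**data.pop("variation", {}))
    frontend = FrontendConfig(**data.pop("frontend", {}))
    return ExperimentConfig(
        data=DataConfig(variation=variation, frontend=frontend, **data),
        training=TrainingConfig(**d.pop("training", {})),
        geometry=GeometryConfig(**d.pop("geometry", {})),
        conditions=tuple(d.pop("conditions", ("clean", "degraded"))),
        **d,
    )


def _cell_seeds(base_seed: int, replicate: int) -> dict[str, int]:
    """Named per-replicate seeds; both condition arms share all of them."""
    state = np.random.SeedSequence([int(base_seed), int(replicate)]).generate_state(5)
    names = ("data", "init", "train", "noise", "geometry")
    return {k: int(v % 2**31) for k, v in zip(names, state)}


def _arm_signature(mcfg: ModelConfig, tcfg: TrainingConfig) -> bytes:
    """Serialized model+training blocks used by the matched-arm audit."""
    payload = {
        "model": {k: v for k, v in dataclasses.asdict(mcfg).items()},
        "training": dataclasses.asdict(tcfg),
    }
    return json.dumps(payload, sort_keys=True).encode()


def _build_splits(cfg: ExperimentConfig, seeds: dict):
    if cfg.data.source == "synthetic":
        raw = generate_dataset(
            n_classes=cfg.data.n_classes,
            exemplars_per_class=cfg.data.exemplars_per_class,
            train_fraction=cfg.data.train_fraction,
            variation=cfg.data.variation,
            seed=seeds["data"],
            n_bands=cfg.data.n_bands,
            n_frames=cfg.data.n_frames,
        )
    elif cfg.data.source == "wav_directory":
        if not cfg.data.wav_root:
            raise ConfigurationError("wav_directory source requires data.wav_root")
        raw = audio_frontend.load_wav_directory(
            cfg.data.wav_root,
            cfg.data.frontend,
            n_frames=cfg.data.n_frames,
            train_fraction=cfg.data.train_fraction,
            seed=seeds["data"],
        )
        if len(raw.lexicon) != cfg.data.n_classes:
            raise ConfigurationError(
                f"data.n_classes={cfg.data.n_classes} but {cfg.data.wav_root} "
                f"holds {len(raw.lexicon)} word folders"
            )
    else:
        raise ConfigurationError(f"unknown data source {cfg.data.source!r}")
    clean, stats = audio_frontend.standardize(raw)
    noise = NoiseConfig(
        sd_multiplier=cfg.noise_sd_multiplier, dataset_sd=1.0, seed=seeds["noise"]
    )
    degraded = audio_frontend.degrade_split(clean, noise)
    return {"clean": clean, "degraded": degraded}, stats


def _geometry_rows(model, split, cfg, seeds, layer_ids, condition, rep, epoch):
    gcfg = cfg.geometry
    registry = model.model_config.conv_layer_registry
    acts = cnn_model.extract_activations(model, split.test, layer_ids)
    rows = []
    for layer in layer_ids:
        ms = manifold_geometry.prepare_manifolds(
            acts.layer(layer), M=gcfg.m_exemplars, N_proj=gcfg.n_proj, seed=seeds["geometry"]
        )
        res = manifold_geometry.mft_analysis(
            ms, n_gaussian_samples=gcfg.n_gaussian_samples, kappa=gcfg.kappa,
            seed=seeds["geometry"] + registry.index(layer),
        )
        pooled = ms.manifolds.reshape(-1, ms.N)
        pr = manifold_geometry.participation_ratio(pooled)
        base = dict(condition=condition, seed=rep, epoch=epoch, layer=layer)
        rows += [
            dict(base, metric="capacity_alpha", value=res.alpha, se=res.alpha_se),
            dict(base, metric="dimension_mft", value=res.dimension, se=np.nan),
            dict(base, metric="radius_mft", value=res.radius, se=np.nan),
            dict(base, metric="participation_ratio", value=pr, se=np.nan),
        ]
    return rows


def _summary_rows(summary, scope, condition, rep, epoch):
    base = dict(condition=condition, seed=rep, epoch=epoch, layer=None)
    return [
        dict(base, metric=f"entropy_bits_{scope}_mean", value=summary.entropy_mean, se=np.nan),
        dict(base, metric=f"entropy_bits_{scope}_sd", value=summary.entropy_sd, se=np.nan),
        dict(base, metric=f"max_prob_{scope}_mean", value=summary.max_prob_mean, se=np.nan),
        dict(base, metric=f"max_prob_{scope}_sd", value=summary.max_prob_sd, se=np.nan),
        dict(base, metric=f"n_{scope}", value=float(summary.n), se=np.nan),
    ]


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Run every condition x replicate cell and collect the tidy table.

    A failure inside one cell is logged as a machine-readable error record
    and the remaining cells proceed.
    """
    rows: list[dict] = []
    cell_errors: list[dict] = []
    all_seeds: dict[int, dict] = {}
    for rep in range(cfg.n_seeds):
        seeds = _cell_seeds(cfg.base_seed, rep)
        all_seeds[rep] = seeds
        try:
            splits, _ = _build_splits(cfg, seeds)
        except Exception as exc:  # data failure aborts the whole replicate
            for condition in cfg.conditions:
                cell_errors.append(
                    {"condition": condition, "seed": rep, "stage": "data", "error": repr(exc)}
                )
            logger.error("replicate=%d stage=data failed: %r", rep, exc)
            continue
        signatures = {}
        for condition in cfg.conditions:
            t0 = time.time()
            try:
                split = splits[condition]
                mcfg = ModelConfig(
                    architecture=cfg.model_architecture,
                    n_classes=cfg.data.n_classes,
                    input_shape=(cfg.data.n_bands, cfg.data.n_frames),
                )
                model = cnn_model.build_model(mcfg, seed=seeds["init"])
                tcfg = replace(cfg.training, seed=seeds["train"])
                signatures[condition] = _arm_signature(mcfg, tcfg)
                final_layer = mcfg.conv_layer_registry[-1]

                def on_epoch_end(epoch, mdl, _condition=condition, _rep=rep, _split=split):
                    if cfg.geometry.epoch_geometry:
                        rows.extend(
                            _geometry_rows(
                                mdl, _split, cfg, seeds, [final_layer], _condition, _rep,
                                epoch + 1,
                            )
                        )

                cnn_model.train(model, split, tcfg, on_epoch_end=on_epoch_end)
                for e, err in enumerate(model.error_curve, start=1):
                    rows.append(
                        dict(condition=condition, seed=rep, epoch=e, layer=None,
                             metric="train_error_pct", value=err, se=np.nan)
                    )
                records = prediction_metrics.evaluate(model, split.test)
                acc = prediction_metrics.accuracy_percent(records)
                final_epoch = cfg.training.epochs
                rows.append(
                    dict(condition=condition, seed=rep, epoch=final_epoch, layer=None,
                         metric="test_accuracy_pct", value=acc, se=np.nan)
                )
                for scope, flag in (("correct", True), ("all", False)):
                    summary = prediction_metrics.summarize_uncertainty(records, correct_only=flag)
                    rows.extend(_summary_rows(summary, scope, condition, rep, final_epoch))
                rows.extend(
                    _geometry_rows(
                        model, split, cfg, seeds, mcfg.conv_layer_registry, condition, rep,
                        final_epoch,
                    )
                )
                logger.info(
                    "condition=%s replicate=%d done in %.1fs (test acc %.1f%%)",
                    condition, rep, time.time() - t0, acc,
                )
            except Exception as exc:
                cell_errors.append(
                    {"condition": condition, "seed": rep, "stage": "cell", "error": repr(exc)}
                )
                logger.error("condition=%s replicate=%d failed: %r", condition, rep, exc)
        if len(signatures) == len(cfg.conditions) and len(set(signatures.values())) > 1:
            raise ConfigurationError(
                "matched-arm audit failed: condition arms differ in model/training blocks"
            )
    table = pd.DataFrame(
        rows, columns=["condition", "seed", "epoch", "layer", "metric", "value", "se"]
    )
    if not table.empty:
        # the final-epoch final-layer geometry is produced by both the
        # epoch-wise callback and the post-training layer sweep, with
        # identical seeds and values; keep one copy
        table = table.drop_duplicates(
            subset=["condition", "seed", "epoch", "layer", "metric"], keep="first"
        )
        table = table.sort_values(
            ["condition", "seed", "epoch", "metric", "layer"], kind="stable"
        ).reset_index(drop=True)
    return ExperimentResult(table=table, config=cfg, seeds=all_seeds, cell_errors=cell_errors)


def _layer_order(cfg: ExperimentConfig) -> list[str]:
    mcfg = ModelConfig(
        architecture=cfg.model_architecture,
        n_classes=cfg.data.n_classes,
        input_shape=(cfg.data.n_bands, cfg.data.n_frames),
    )
    cnn_model.build_model(mcfg, seed=0)
    return mcfg.conv_layer_registry


def write_report(result: ExperimentResult, outdir) -> dict:
    """Write the figure source tables, summary.json and the run manifest.

    Returns a manifest dict mapping logical names to file paths.
    """
    import os

    if result.table.empty:
        raise InvalidInputError("cannot report an empty result")
    os.makedirs(outdir, exist_ok=True)
    t = result.table
    registry = _layer_order(result.config)
    layer_index = {l: i for i, l in enumerate(registry)}
    final_epoch = result.config.training.epochs

    def _wide(sub: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
        wide = sub.pivot_table(
            index=keys, columns="metric", values="value", aggfunc="first"
        ).reset_index()
        wide.columns.name = None
        return wide

    paths = {}

    fig3a = t[t.metric == "train_error_pct"][["condition", "seed", "epoch", "value"]]
    fig3a = fig3a.rename(columns={"value": "error_pct"}).sort_values(
        ["condition", "seed", "epoch"]
    )
    paths["fig3a"] = os.path.join(outdir, "fig3a_training_error.csv")
    fig3a.to_csv(paths["fig3a"], index=False)

    unc_metrics = [m for m in t.metric.unique() if m.startswith(("entropy", "max_prob", "n_"))]
    unc = t[t.metric.isin(unc_metrics + ["test_accuracy_pct"]) & t.layer.isna()]
    fig3bc = _wide(unc, ["condition", "seed"]).sort_values(["condition", "seed"])
    paths["fig3bc"] = os.path.join(outdir, "fig3bc_uncertainty.csv")
    fig3bc.to_csv(paths["fig3bc"], index=False)

    geo = t[t.layer.notna()].copy()
    final_layer = registry[-1]
    fig4 = geo[geo.layer == final_layer]
    fig4 = _wide(fig4, ["condition", "seed", "epoch"]).sort_values(
        ["condition", "seed", "epoch"]
    )
    paths["fig4"] = os.path.join(outdir, "fig4_epoch_geometry.csv")
    fig4.to_csv(paths["fig4"], index=False)

    fig5 = geo[geo.epoch == final_epoch].copy()
    fig5["layer_index"] = fig5.layer.map(layer_index)
    fig5 = _wide(fig5, ["condition", "seed", "layer_index", "layer"]).sort_values(
        ["condition", "seed", "layer_index"]
    )
    paths["fig5"] = os.path.join(outdir, "fig5_layer_geometry.csv")
    fig5.to_csv(paths["fig5"], index=False)

    summary = {}
    for condition in sorted(t.condition.unique()):
        sub = t[t.condition == condition]
        final_err = sub[(sub.metric == "train_error_pct") & (sub.epoch == final_epoch)].value
        acc = sub[sub.metric == "test_accuracy_pct"].value
        ent = sub[sub.metric == "entropy_bits_correct_mean"].value
        mp = sub[sub.metric == "max_prob_correct_mean"].value
        alpha = sub[(sub.metric == "capacity_alpha") & (sub.layer == final_layer)
                    & (sub.epoch == final_epoch)].value
        dim = sub[(sub.metric == "dimension_mft") & (sub.layer == final_layer)
                  & (sub.epoch == final_epoch)].value

        def stat(v):
            v = np.asarray(v, dtype=float)
            if v.size == 0:
                return {"mean": None, "sd": None}
            return {"mean": float(v.mean()),
                    "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0}

        summary[condition] = {
            "final_train_error_pct": stat(final_err),
            "final_train_accuracy_pct": stat(100.0 - np.asarray(final_err, dtype=float)),
            "test_accuracy_pct": stat(acc),
            "entropy_bits_correct": stat(ent),
            "max_prob_correct": stat(mp),
            "final_layer_capacity_alpha": stat(alpha),
            "final_layer_dimension": stat(dim),
        }
    paths["summary"] = os.path.join(outdir, "summary.json")
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    cfg_dict = config_to_dict(result.config)
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seeds": {str(k): v for k, v in result.seeds.items()},
        "cell_errors": result.cell_errors,
        "files": {k: os.path.basename(v) for k, v in paths.items()},
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    paths["manifest"] = os.path.join(outdir, "manifest.json")
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    paths["tidy"] = os.path.join(outdir, "tidy_results.csv")
    result.table.to_csv(paths["tidy"], index=False)
    return paths
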