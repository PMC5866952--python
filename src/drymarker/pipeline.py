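"""End-to-end orchestration: tolerance scoring -> preprocessing -> Random-
Forest training and marker selection -> independent-trial validation.

:func:`run_pipeline` drives the whole analysis on a simulated dataset (or
one loaded from TSV files), mirroring the study layout: models are trained
on experimental-trial samples, marker panels extracted by backward
elimination with the 1-SE rule, and both the full and the reduced model
are validated on agronomic-trial samples that never entered training.
Metabolite and transcript blocks are analysed separately and, on their
shared samples, combined.

Every stage is seeded; a report bundle (JSON summary plus TSV tables) is
written when an output directory is configured, and re-running with the
same configuration and seed reproduces it byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess, rf
from .containers import FeatureMatrix
from .evaluate import confusion, per_trial_accuracy
from .simulate import SimulatedDataset, SimulationDesign, simulate_dataset
from .tolerance import score_yield_table, scores_to_frame

logger = logging.getLogger("drymarker")

__all__ = ["PipelineConfig", "run_pipeline", "preprocess_block"]


@dataclasses.dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    design: SimulationDesign = dataclasses.field(default_factory=SimulationDesign)
    seed: int = 0
    ntree: int = 1000
    mtry: int | str | None = None
    drop_fraction: float = 0.2
    min_features: int = 2
    n_components: int = 2  # NIPALS components for imputation
    blocks: tuple = ("metabolite", "transcript", "combined")
    validate: bool = True
    out_dir: str | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        design = SimulationDesign(**raw.pop("design", {}))
        blocks = tuple(raw.pop("blocks", ("metabolite", "transcript", "combined")))
        return cls(design=design, blocks=blocks, **raw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


def preprocess_block(fm: FeatureMatrix, block: str, n_components: int = 5) -> FeatureMatrix:
    """Block-appropriate preprocessing to a complete, model-ready matrix.

    Metabolite intensities are log10-transformed and ANOVA-corrected for
    batch, run order and per-sample response; transcript values arrive
    already normalized on the log scale and are only imputed. Both blocks
    end with NIPALS imputation.
    """
    if block == "metabolite":
        fm = preprocess.log_transform(fm, base=10)
        fm = preprocess.anova_correct(fm)
    return preprocess.nipals_impute(fm, n_components=n_components)


def _train_and_validate(
    fm: FeatureMatrix,
    class_of_cultivar: pd.Series,
    cfg: PipelineConfig,
    seed: int,
    do_validate: bool,
) -> dict:
    """Shared per-block analysis on a complete matrix."""
    labels = fm.meta["cultivar"].map(class_of_cultivar)
    is_train = fm.meta["trial_type"] == "experimental"
    train = fm.subset(samples=fm.sample_ids[is_train])
    y_train = labels[is_train]

    trace = rf.backward_eliminate(
        train,
        y_train,
        drop_fraction=cfg.drop_fraction,
        min_features=cfg.min_features,
        ntree=cfg.ntree,
        mtry=cfg.mtry,
        seed=seed,
    )
    full_fit = rf.train_rf(train, y_train, ntree=cfg.ntree, mtry=cfg.mtry, seed=seed)
    panel = trace.chosen.feature_ids
    reduced_fit = rf.train_rf(
        train.subset(features=panel), y_train, ntree=cfg.ntree, mtry=cfg.mtry, seed=seed
    )
    result = {
        "n_train": int(train.n_samples),
        "n_features": int(train.n_features),
        "oob_error_full": full_fit.oob_error,
        "oob_error_reduced": reduced_fit.oob_error,
        "panel_size": len(panel),
        "panel": sorted(panel),
        "trace": trace,
        "full_fit": full_fit,
        "reduced_fit": reduced_fit,
    }

    if do_validate and (~is_train).any():
        valid = fm.subset(samples=fm.sample_ids[~is_train])
        y_valid = labels[~is_train]
        for name, fit in (("full", full_fit), ("reduced", reduced_fit)):
            vm = valid if name == "full" else valid.subset(features=panel)
            pred = rf.predict(fit, vm)
            summary = confusion(pred.to_numpy(), y_valid.to_numpy())
            result[f"validation_{name}"] = summary
            result[f"validation_accuracy_{name}"] = summary.overall_accuracy
        result["per_trial_accuracy"] = per_trial_accuracy(
            rf.predict(full_fit, valid).to_numpy(),
            y_valid.to_numpy(),
            valid.meta["trial"].to_numpy(),
        )
        result["n_validation"] = int(valid.n_samples)
    return result


def _combined_matrix(met: FeatureMatrix, tr: FeatureMatrix) -> FeatureMatrix:
    """Join the two blocks on their shared samples (suffix-free feature ids)."""
    shared = met.sample_ids.intersection(tr.sample_ids)
    if len(shared) == 0:
        raise ValueError("metabolite and transcript blocks share no samples")
    values = pd.concat(
        [met.values.loc[shared], tr.values.loc[shared]], axis=1
    )
    return FeatureMatrix(values, met.meta.loc[shared].copy())


def run_pipeline(config: PipelineConfig | dict | None = None, dataset: SimulatedDataset | None = None) -> dict:
    """Execute the full marker-discovery workflow and return the report.

    With no ``dataset``, one is simulated from ``config.design`` and
    ``config.seed``. The report maps stage names to their results
    (tolerance table, stress indices, per-block model summaries); when
    ``config.out_dir`` is set, TSV/JSON artifacts are also written there.
    """
    if config is None:
        config = PipelineConfig()
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    if dataset is None:
        logger.info("simulating dataset (seed=%d)", config.seed)
        dataset = simulate_dataset(config.design, seed=config.seed)

    # --- tolerance scoring from yields ---------------------------------
    logger.info("scoring drought tolerance from %d yield records", len(dataset.yields))
    scores, stress_indices = score_yield_table(dataset.yields)
    tol_frame = scores_to_frame(scores)
    class_of_cultivar = tol_frame["tolerance_class"]

    report: dict = {
        "seed": config.seed,
        "tolerance": tol_frame,
        "stress_index": {s.trial_id: s.si for s in stress_indices},
        "blocks": {},
    }
    if dataset.truth is not None:
        agreement = np.mean(
            [class_of_cultivar[c] == dataset.truth.true_class[c] for c in class_of_cultivar.index]
        )
        report["class_recovery"] = float(agreement)

    # --- preprocessing ---------------------------------------------------
    blocks: dict[str, FeatureMatrix] = {}
    if {"metabolite", "combined"} & set(config.blocks):
        logger.info("preprocessing metabolite block")
        blocks["metabolite"] = preprocess_block(
            dataset.metabolites, "metabolite", config.n_components
        )
    if {"transcript", "combined"} & set(config.blocks):
        logger.info("preprocessing transcript block")
        blocks["transcript"] = preprocess_block(
            dataset.transcripts, "transcript", config.n_components
        )
    if "combined" in config.blocks:
        blocks["combined"] = _combined_matrix(blocks["metabolite"], blocks["transcript"])

    # --- per-block training, selection, validation ----------------------
    rng = np.random.SeedSequence(config.seed)
    block_seeds = {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(("metabolite", "transcript", "combined"), rng.spawn(3))
    }
    for name in config.blocks:
        fm = blocks[name]
        logger.info(
            "block %s: %d samples x %d features", name, fm.n_samples, fm.n_features
        )
        result = _train_and_validate(
            fm, class_of_cultivar, config, block_seeds[name], config.validate
        )
        if dataset.truth is not None and name in ("metabolite", "transcript"):
            planted = set(dataset.truth.informative_features.get(name, []))
            if planted:
                hit = len(planted & set(result["panel"]))
                result["panel_recovery"] = hit / len(planted)
        report["blocks"][name] = result

    if config.out_dir:
        _write_report(report, config)
    return report


def _json_safe(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, dict):
        return {k: _json_safe(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_json_safe(v) for v in value]
    return value


def _write_report(report: dict, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report["tolerance"].to_csv(out / "tolerance.tsv", sep="\t")
    summary: dict = {
        "seed": report["seed"],
        "stress_index": report["stress_index"],
        "blocks": {},
    }
    if "class_recovery" in report:
        summary["class_recovery"] = report["class_recovery"]
    for name, result in report["blocks"].items():
        result["trace"].to_tsv(out / f"{name}_selection_trace.tsv")
        block_summary = {
            k: _json_safe(v)
            for k, v in result.items()
            if isinstance(v, (int, float, str, list, np.floating, np.integer))
        }
        for key in ("validation_full", "validation_reduced"):
            if key in result:
                block_summary[key] = result[key].to_dict()
                result[key].to_frame().to_csv(out / f"{name}_{key}.tsv", sep="\t")
        if "per_trial_accuracy" in result:
            result["per_trial_accuracy"].to_csv(out / f"{name}_per_trial_accuracy.tsv", sep="\t")
            block_summary["per_trial_accuracy"] = {
                str(k): v for k, v in result["per_trial_accuracy"]["accuracy"].items()
            }
        summary["blocks"][name] = block_summary
    (out / "summary.json").write_text(json.dumps(_json_safe(summary), indent=2, sort_keys=True))
    logger.info("report written to %s", out)
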