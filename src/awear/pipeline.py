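"""End-to-end study orchestration.

``run_study`` executes the full chain in memory — synthesize cohort,
preprocess, extract features, ANOVA-rank and select, KNN on a stratified
hold-out, batch SOM on all subjects — and returns every intermediate object.
``run_pipeline`` wraps it with artifact serialization (cohort CSVs, feature
tables, ranking, evaluation reports, optional figures, a summary JSON) into
a run directory.

One global seed fans out to per-stage seeds by fixed offsets so any stage
can be re-run in isolation; two runs from the same config are identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd
import yaml

from . import io as awio
from .classify import SplitSpec, evaluate, knn_fit_predict, som_fit, som_predict, stratified_holdout_split
from .features import BandSpec, FeatureConfig, PRESET_BANDS, build_feature_table
from .preprocess import FilterSpec, preprocess_recording
from .selection import anova_rank, select_features
from .synth import CohortSpec, generate_cohort

__all__ = ["PipelineConfig", "run_study", "run_pipeline"]

logger = logging.getLogger("awear")

# fixed per-stage seed offsets (re-runnable stages under one global seed)
_SPLIT_OFFSET = 10_000
_SOM_OFFSET = 20_000


@dataclass
class PipelineConfig:
    """Everything that determines a study run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    filter: FilterSpec = field(default_factory=FilterSpec)
    hampel_window: int = 11
    hampel_n_mad: float = 3.0
    features: FeatureConfig = field(default_factory=FeatureConfig)
    select_k: int = 24
    holdout_fraction: float = 0.30
    knn_k: int = 10
    som_neurons: int = 3
    som_epochs: int = 200
    seed: int = 0
    make_plots: bool = False
    save_recordings: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        if "cohort" in raw:
            cfg.cohort = CohortSpec(**{
                k: (tuple(v) if k == "tasks" else v) for k, v in raw["cohort"].items()
            })
        if "filter" in raw:
            cfg.filter = FilterSpec(**raw["filter"])
        if "features" in raw:
            fr = dict(raw["features"])
            if "bands" in fr:
                fr["bands"] = tuple(
                    PRESET_BANDS[b] if isinstance(b, str) else BandSpec(**b)
                    for b in fr["bands"]
                )
            if "search_band" in fr:
                fr["search_band"] = tuple(fr["search_band"])
            cfg.features = FeatureConfig(**fr)
        for key in (
            "hampel_window",
            "hampel_n_mad",
            "select_k",
            "holdout_fraction",
            "knn_k",
            "som_neurons",
            "som_epochs",
            "seed",
            "make_plots",
            "save_recordings",
        ):
            if key in raw:
                setattr(cfg, key, raw[key])
        cfg.cohort.seed = cfg.seed
        return cfg


def run_study(config: PipelineConfig) -> Dict:
    """Run the full study in memory; returns all intermediate objects.

    Keys: recordings, filtered, feature_table, ranking, reduced_table,
    train/test tables, knn_report, som, som_predictions, som_report,
    som_correct_count, summary.
    """
    cohort = dataclasses.replace(config.cohort, seed=config.seed)
    logger.info(
        "run: filter order=%d band=%.1f-%.1f Hz zero_phase=%s, hampel w=%d nmad=%.1f, "
        "ApEn m=%d r=%.2fxSD, k_select=%d, KNN k=%d holdout=%.2f, SOM %dx1 %d epochs",
        config.filter.order, config.filter.low_cut_hz, config.filter.high_cut_hz,
        config.filter.zero_phase, config.hampel_window, config.hampel_n_mad,
        config.features.apen_m, config.features.apen_r_factor, config.select_k,
        config.knn_k, config.holdout_fraction, config.som_neurons, config.som_epochs,
    )
    recordings, labels = generate_cohort(cohort)
    n_classes = len(set(labels))
    if n_classes < 3:
        logger.warning("cohort has only %d class(es); running as a %d-class problem",
                       n_classes, n_classes)
    filtered = [
        preprocess_recording(
            rec, config.filter, window=config.hampel_window, n_mad=config.hampel_n_mad
        )
        for rec in recordings
    ]
    table = build_feature_table(filtered, labels, config.features)
    ranking = anova_rank(table)
    k = min(config.select_k, len(ranking))
    reduced = select_features(ranking, table, k)

    train, test = stratified_holdout_split(
        reduced,
        SplitSpec(
            holdout_fraction=config.holdout_fraction,
            stratified=True,
            seed=config.seed + _SPLIT_OFFSET,
        ),
    )
    preds, scores = knn_fit_predict(train, test, k=config.knn_k)
    knn_report = evaluate(test["class_label"].to_numpy(), preds, scores)

    som = som_fit(
        reduced,
        n_neurons=config.som_neurons,
        n_epochs=config.som_epochs,
        seed=config.seed + _SOM_OFFSET,
    )
    som_preds = som_predict(som, reduced)
    y_all = reduced["class_label"].to_numpy()
    som_report = evaluate(y_all, som_preds)
    som_correct = int((som_preds == y_all).sum())

    summary = {
        "seed": config.seed,
        "n_subjects": len(table),
        "n_features": len(ranking),
        "selected_k": k,
        "knn_accuracy": knn_report.accuracy,
        "knn_sensitivity": knn_report.sensitivity,
        "knn_specificity": knn_report.specificity,
        "som_correct_count": som_correct,
        "som_mse": som.mse_,
        "som_sample_hits": som.sample_hits_.tolist(),
        "top_features": ranking["feature"].head(k).tolist(),
    }
    return {
        "recordings": recordings,
        "labels": labels,
        "filtered": filtered,
        "feature_table": table,
        "ranking": ranking,
        "reduced_table": reduced,
        "train": train,
        "test": test,
        "knn_predictions": preds,
        "knn_scores": scores,
        "knn_report": knn_report,
        "som": som,
        "som_predictions": som_preds,
        "som_report": som_report,
        "som_correct_count": som_correct,
        "summary": summary,
    }


def _save_plots(result: Dict, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .features import welch_psd

    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)

    # before/after preprocessing, first recording, ax channel
    raw = result["recordings"][0]
    filt = result["filtered"][0]
    fig, axes = plt.subplots(2, 2, figsize=(10, 6))
    axes[0, 0].plot(raw.t, raw.ax, lw=0.3)
    axes[0, 0].set_title(f"{raw.subject_id} {raw.task} ax raw")
    axes[0, 1].plot(filt.t, filt.ax, lw=0.3)
    axes[0, 1].set_title("filtered (2-20 Hz)")
    est_raw = welch_psd(raw.ax, raw.sampling_rate_hz)
    est_f = welch_psd(filt.ax, filt.sampling_rate_hz)
    axes[1, 0].semilogy(est_raw.frequencies, est_raw.psd)
    axes[1, 0].set_xlabel("Hz")
    axes[1, 1].semilogy(est_f.frequencies, np.maximum(est_f.psd, 1e-20))
    axes[1, 1].set_xlabel("Hz")
    fig.tight_layout()
    fig.savefig(figdir / "preprocessing_before_after.png", dpi=100)
    plt.close(fig)

    # feature histograms by class for the top-ranked features
    table = result["feature_table"]
    top = result["ranking"]["feature"].head(6).tolist()
    fig, axes = plt.subplots(2, 3, figsize=(12, 6))
    for ax_, feat in zip(axes.ravel(), top):
        for label, grp in table.groupby("class_label"):
            ax_.hist(grp[feat], bins=10, alpha=0.5, label=label)
        ax_.set_title(feat, fontsize=8)
    axes[0, 0].legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(figdir / "feature_histograms.png", dpi=100)
    plt.close(fig)

    # SOM sample hits
    som = result["som"]
    fig, ax_ = plt.subplots(figsize=(4, 3))
    ax_.bar(range(som.n_neurons), som.sample_hits_)
    ax_.set_xticks(range(som.n_neurons))
    ax_.set_xticklabels(som.neuron_labels_, rotation=20)
    ax_.set_ylabel("sample hits")
    fig.tight_layout()
    fig.savefig(figdir / "som_sample_hits.png", dpi=100)
    plt.close(fig)


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run the study and serialize every artifact into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        result = run_study(config)
        if config.save_recordings:
            for sub, recs in (("cohort", result["recordings"]),
                              ("filtered", result["filtered"])):
                d = out / sub
                d.mkdir(exist_ok=True)
                for rec in recs:
                    awio.write_recording(rec, d / awio.recording_filename(rec))
        awio.write_feature_table(result["feature_table"], out / "features.csv")
        result["ranking"].to_csv(out / "anova_ranking.csv", index=False)
        awio.write_feature_table(result["reduced_table"], out / "features_selected.csv")
        with open(out / "knn_report.json", "w") as fh:
            json.dump(result["knn_report"].to_dict(), fh, indent=2)
        with open(out / "som_report.json", "w") as fh:
            json.dump(result["som_report"].to_dict(), fh, indent=2)
        pd.DataFrame(
            result["knn_report"].confusion_matrix,
            index=result["knn_report"].classes,
            columns=result["knn_report"].classes,
        ).to_csv(out / "knn_confusion_matrix.csv")
        with open(out / "summary.json", "w") as fh:
            json.dump(result["summary"], fh, indent=2, sort_keys=True)
        if config.make_plots:
            try:
                _save_plots(result, out)
            except ImportError:
                logger.warning("matplotlib unavailable; skipping figures")
        return out
    finally:
        logger.removeHandler(handler)
        handler.close()
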