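"""End-to-end orchestration and artifact export.

``run_pipeline`` drives the whole analysis from one config: per-group
score tables (read from CSV or generated from a synthetic preset), the
missingness filter, score-probability conversion, sequence/subtype
fitting with optional CVIC selection, subject assignment, cross-group
classification (winner-takes-all and logistic), heuristic-staging
comparison, and cohort statistics.  Every output is regenerable from the
config plus the seed; a manifest records versions, seed, and config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import replace
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
import yaml

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from scipy.special import softmax

from .assignment import (
    assign_subtype_and_stage,
    assignments_frame,
    cross_validated_stage_logliks,
    joint_classification_probabilities,
    model_avg_stage_loglik,
)
from .classifier import (
    LogisticConfig,
    accuracy_excluding_unclassified,
    classification_metrics,
    classify_logistic,
    classify_max_likelihood,
)
from .inference import FitConfig, cross_validate_cvic, fit_subtypes
from .io import (
    RegionalScoreTable,
    filter_regions_by_missingness,
    read_metadata,
    read_score_table,
    total_pathology_all,
    write_score_table,
)
from .progression import SubtypeModel, build_event_set
from .score_model import ratings_to_probabilities
from .staging import builtin_scheme, compare_to_sustain, stage_subjects
from .stats import (
    classifiable_vs_unclassifiable_test,
    regionwise_subtype_glm,
    stage_association,
)
from .synthetic import generate_cohort, preset, restrict_config

log = logging.getLogger("tdpstage")

_LEVEL_COLORS = {1: (0.85, 0.11, 0.10), 2: (0.55, 0.25, 0.65),
                 3: (0.13, 0.25, 0.70)}  # light / moderate / severe


def export_positional_variance(
    model: SubtypeModel, out_prefix: str | Path
) -> list[Path]:
    """Write each subtype's event x stage frequency matrix as CSV + heatmap.

    Rows are 'region:level' events in canonical order; cell colour encodes
    the score level (red = mild, purple = moderate, blue = severe) with
    intensity proportional to positional frequency.
    """
    if not any(model.mcmc_samples):
        raise ValueError("model has no MCMC samples to summarise")
    from .inference import positional_density

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    es = model.event_set
    tokens = [f"{es.region_names[r]}:{s}" for r, s in es.events]
    written = []
    for c, samples in enumerate(model.mcmc_samples):
        density = positional_density(es, samples)
        df = pd.DataFrame(
            density, index=pd.Index(tokens, name="event"),
            columns=[f"stage_{k + 1}" for k in range(es.n_events)],
        )
        csv_path = out_prefix.with_name(
            f"{out_prefix.name}_subtype{c + 1}.csv"
        )
        df.to_csv(csv_path)
        img = np.ones((es.n_events, es.n_events, 3))
        for row, (_, s) in enumerate(es.events):
            color = np.array(_LEVEL_COLORS[min(s, 3)])
            f = density[row][:, None]
            img[row] = (1 - f) + f * color[None, :]
        fig, ax = plt.subplots(
            figsize=(max(4, es.n_events * 0.18), max(3, es.n_events * 0.14))
        )
        ax.imshow(img, aspect="auto", interpolation="nearest")
        ax.set_yticks(range(es.n_events), tokens, fontsize=5)
        ax.set_xlabel("stage")
        ax.set_title(f"{model.group_label} subtype {c + 1}")
        png_path = csv_path.with_suffix(".png")
        fig.tight_layout()
        fig.savefig(png_path, dpi=150)
        plt.close(fig)
        written += [csv_path, png_path]
    return written


def export_stage_histogram(
    assignments_df: pd.DataFrame, n_stages: int, out_prefix: str | Path
) -> list[Path]:
    """Counts per maximum-likelihood stage, as CSV and bar plot."""
    out_prefix = Path(out_prefix)
    counts = (
        assignments_df["ml_stage"].value_counts()
        .reindex(range(n_stages), fill_value=0).sort_index()
    )
    csv_path = out_prefix.with_suffix(".csv")
    counts.rename("count").to_csv(csv_path, index_label="stage")
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.bar(counts.index, counts.to_numpy())
    ax.set_xlabel("stage")
    ax.set_ylabel("subjects")
    fig.tight_layout()
    png_path = out_prefix.with_suffix(".png")
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
    return [csv_path, png_path]


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _group_table(gcfg: dict, seed: int, out: Path):
    """Score table + metadata for one group, from CSV or a preset."""
    name = gcfg["name"]
    if "scores_csv" in gcfg:
        table = read_score_table(gcfg["scores_csv"], gcfg.get("schema"))
        meta = (
            read_metadata(gcfg["metadata_csv"])
            if "metadata_csv" in gcfg else None
        )
        return table, meta, None
    cfg = preset(gcfg["preset"], seed=seed)
    if "regions" in gcfg:
        cfg = restrict_config(cfg, gcfg["regions"])
    overrides = {
        k: gcfg[k]
        for k in ("n_subjects", "noise_epsilon", "stage_distribution")
        if k in gcfg
    }
    if overrides:
        cfg = replace(cfg, **overrides)
    table, meta, truth = generate_cohort(cfg)
    write_score_table(table, out / f"{name}_scores.csv")
    truth.to_csv(out / f"{name}_truth.csv")
    return table, meta, truth


def run_pipeline(config, out_dir: str | Path, seed: int = 0) -> dict:
    """Execute the full analysis; returns a dict of in-memory results.

    Config keys: ``groups`` (list of {name, preset|scores_csv, ...}),
    ``sigma``, ``missingness_threshold``, ``max_subtypes``, ``fit`` (FitConfig
    overrides), ``logistic`` (LogisticConfig overrides), ``schemes``
    (group name -> bundled scheme name), ``make_plots``.
    """
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    fit_cfg = FitConfig(**{**cfg.get("fit", {}), "seed": seed})
    sigma = cfg.get("sigma", 0.5)
    threshold = cfg.get("missingness_threshold", 0.25)
    max_subtypes = cfg.get("max_subtypes", 1)
    make_plots = cfg.get("make_plots", True)

    results: dict = {"groups": {}, "seed": seed}
    group_order = [g["name"] for g in cfg["groups"]]

    for gcfg in cfg["groups"]:
        name = gcfg["name"]
        log.info("group %s: reading/generating data", name)
        table, meta, truth = _group_table(gcfg, seed, out)
        filtered, excluded = filter_regions_by_missingness(table, threshold)
        probs = ratings_to_probabilities(filtered, sigma)
        event_set = build_event_set(filtered.region_names)

        n_subtypes = 1
        cvic = None
        if max_subtypes > 1:
            cvic = cross_validate_cvic(
                probs, event_set, max_subtypes, fit_cfg, rng
            )
            n_subtypes = cvic.selected
        model = fit_subtypes(
            probs, event_set, n_subtypes, fit_cfg, rng, group_label=name
        )
        assignments = assign_subtype_and_stage(probs, model)
        adf = assignments_frame(assignments)
        adf.to_csv(out / f"{name}_assignments.csv")
        with open(out / f"{name}_model.json", "w") as fh:
            json.dump(model.to_dict(), fh)
        if make_plots:
            export_positional_variance(model, out / f"{name}_positional")
            export_stage_histogram(
                adf, event_set.n_events + 1, out / f"{name}_stage_histogram"
            )

        gres = {
            "table": table, "filtered": filtered, "excluded": excluded,
            "probs": probs, "model": model, "assignments": assignments,
            "assignments_df": adf, "metadata": meta, "truth": truth,
        }
        if cvic is not None:
            gres["cvic"] = cvic
            pd.DataFrame(
                {"C": np.arange(1, max_subtypes + 1), "CVIC": cvic.cvic}
            ).to_csv(out / f"{name}_cvic.csv", index=False)

        stats_rows = {}
        total = total_pathology_all(filtered)
        stats_rows["total_pathology"] = stage_association(assignments, total)
        if meta is not None:
            for var in ("age_at_onset", "age_at_death", "disease_duration"):
                try:
                    stats_rows[var] = stage_association(
                        assignments, meta[var]
                    )
                except (ValueError, KeyError) as exc:
                    log.warning("%s: %s skipped (%s)", name, var, exc)
        gres["stage_associations"] = pd.DataFrame(
            stats_rows, index=["r", "p"]
        ).T
        gres["stage_associations"].to_csv(out / f"{name}_associations.csv")

        if model.n_subtypes >= 2:
            glm = regionwise_subtype_glm(filtered, assignments)
            glm.to_csv(out / f"{name}_subtype_glm.csv")
            gres["subtype_glm"] = glm

        scheme_name = cfg.get("schemes", {}).get(name)
        if scheme_name:
            scheme = builtin_scheme(scheme_name)
            heur = stage_subjects(filtered, scheme)
            heur.to_csv(out / f"{name}_heuristic_stages.csv")
            agreement = compare_to_sustain(heur["stage"], assignments, scheme)
            agreement.crosstab.to_csv(out / f"{name}_stage_agreement.csv")
            gres["heuristic"] = heur
            gres["agreement"] = agreement
        results["groups"][name] = gres

    if len(group_order) >= 2:
        results["classification"] = _classify_groups(
            results["groups"], group_order, fit_cfg, cfg, out, rng, sigma
        )
        for name, gres in results["groups"].items():
            if "heuristic" in gres and "cv_fit_probability" in gres:
                try:
                    t_stat, p_val = classifiable_vs_unclassifiable_test(
                        gres["heuristic"]["stage"], gres["cv_fit_probability"]
                    )
                    gres["unclassifiable_test"] = (t_stat, p_val)
                except ValueError as exc:
                    log.warning("%s: unclassifiable t-test skipped (%s)",
                                name, exc)

    manifest = {
        "tdpstage_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "groups": group_order,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return results


def cross_group_probabilities(
    tables: dict[str, RegionalScoreTable],
    models: dict[str, SubtypeModel],
    fit_cfg: FitConfig,
    rng: np.random.Generator,
    sigma: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Evaluate every cohort under every group model.

    Each cohort is scored on each model's own region set (regions a cohort
    never sampled enter as uniform, like any missing rating); the cohort's
    own-group stage likelihoods are 10-fold cross-validated.  Returns the
    jointly normalised (group, stage) max probabilities, their argmax
    stages, the within-model maximum-likelihood-stage probabilities, and a
    group -> subject -> fold-model map.
    """
    group_order = list(models)
    subject_ids = [s for name in group_order for s in tables[name].subject_ids]
    avg_logliks, region_counts, within_probs = {}, {}, {}
    cv_fold_models: dict = {}
    for model_name in group_order:
        model = models[model_name]
        regions = list(model.event_set.region_names)
        region_counts[model_name] = len(regions)
        blocks = []
        for name in group_order:
            raw = tables[name].scores.reindex(columns=regions)
            tensor = ratings_to_probabilities(
                RegionalScoreTable(raw, tables[name].groups), sigma
            )
            if name == model_name:
                block, fold_models = cross_validated_stage_logliks(
                    tensor, model, fit_cfg, rng
                )
                cv_fold_models[name] = fold_models
            else:
                block = model_avg_stage_loglik(tensor, model)
            blocks.append(block)
        avg_logliks[model_name] = np.concatenate(blocks, axis=0)
        post = softmax(avg_logliks[model_name], axis=1)
        within_probs[model_name] = post.max(axis=1)

    universe = len({r for m in models.values()
                    for r in m.event_set.region_names})
    fit_probs, ml_stages = joint_classification_probabilities(
        avg_logliks, region_counts, subject_ids, universe
    )
    within = pd.DataFrame(within_probs, index=subject_ids)[group_order]
    return fit_probs[group_order], ml_stages[group_order], within, cv_fold_models


def _classify_groups(groups, group_order, fit_cfg, cfg, out, rng, sigma=0.5):
    """Cross-group classification over the pooled cohorts.

    Winner-takes-all uses the jointly normalised (group, stage)
    probabilities; the logistic model uses the within-model
    maximum-likelihood-stage probabilities plus stage and age at death.
    """
    labels, ages, subject_ids = [], [], []
    for name in group_order:
        g = groups[name]
        subject_ids += g["table"].subject_ids
        labels += [name] * g["table"].n_subjects
        if g["metadata"] is not None:
            ages += list(g["metadata"]["age_at_death"])
    labels = pd.Series(labels, index=subject_ids, name="true")

    fit_probs, ml_stages, within, cv_fold_models = cross_group_probabilities(
        {name: groups[name]["table"] for name in group_order},
        {name: groups[name]["model"] for name in group_order},
        fit_cfg, rng, sigma,
    )
    for name in group_order:
        groups[name]["cv_fold_models"] = cv_fold_models[name]
    fit_probs.to_csv(out / "classification_probabilities.csv")
    within.to_csv(out / "fit_probabilities.csv")
    for name in group_order:
        g = groups[name]
        own = within.loc[g["table"].subject_ids, name]
        g["cv_fit_probability"] = own

    predicted = classify_max_likelihood(fit_probs, ml_stages)
    wta_acc = accuracy_excluding_unclassified(labels, predicted)
    classified = predicted != "Unclassified"
    cm, metrics = classification_metrics(
        labels[classified], predicted[classified]
    )
    cm.to_csv(out / "wta_confusion.csv")

    result = {
        "fit_probs": fit_probs, "ml_stages": ml_stages,
        "within_model_probs": within,
        "true_labels": labels, "wta_predicted": predicted,
        "wta_accuracy": wta_acc, "wta_confusion": cm, "wta_metrics": metrics,
    }

    if ages and len(ages) == len(subject_ids):
        winner = fit_probs.to_numpy().argmax(axis=1)
        own_stage = ml_stages.to_numpy()[np.arange(len(winner)), winner]
        features = within.copy()
        features["ml_stage"] = own_stage
        features["age_at_death"] = ages
        lcfg = LogisticConfig(
            **{**cfg.get("logistic", {}), "seed": int(rng.integers(2**31))}
        )
        logistic = classify_logistic(
            features[classified], labels[classified], lcfg
        )
        logistic.split_metrics.to_csv(out / "logistic_metrics.csv", index=False)
        logistic.mean_confusion.to_csv(out / "logistic_confusion.csv")
        result["logistic"] = logistic
    return result
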