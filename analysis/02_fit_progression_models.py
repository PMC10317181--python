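#!/usr/bin/env python
"""Fit one progression model per cohort and export staging artifacts.

Reads the cohorts written by 01_simulate_cohorts.py, applies the >25%
missingness region filter, converts ratings to score probabilities, fits
a single progression sequence per group with MCMC uncertainty, assigns
every subject a maximum-likelihood stage, and writes models, assignments,
stage histograms, positional variance diagrams and stage-age/-pathology
correlations under results/models/.

This driver runs the fit on a reduced 10-region panel per group (the
regions earliest in each group's true sequence plus shared late regions)
so the whole analysis finishes in a few minutes; the library handles the
full 21-region battery identically.

Run:  python analysis/02_fit_progression_models.py [--seed 1]
"""

import argparse
import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from tdpstage.assignment import assign_subtype_and_stage, assignments_frame
from tdpstage.inference import FitConfig, fit_subtypes
from tdpstage.io import (
    filter_regions_by_missingness,
    read_metadata,
    read_score_table,
    total_pathology_all,
)
from tdpstage.pipeline import export_positional_variance, export_stage_histogram
from tdpstage.progression import build_event_set
from tdpstage.score_model import ratings_to_probabilities
from tdpstage.stats import stage_association

PANEL = ["amygdala", "ca_subiculum", "entorhinal_cortex",
         "anterior_cingulate", "superior_middle_temporal", "middle_frontal",
         "thalamus", "medulla", "motor_cortex", "spinal_cord"]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--cohorts", type=Path, default=Path("results/cohorts"))
    parser.add_argument("--out", type=Path, default=Path("results/models"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    fit_cfg = FitConfig(n_starts=5, mcmc_iterations=5000,
                        max_stored_samples=500, seed=args.seed)
    for stem in ("ALS", "FTLD_TDP", "LATE_NC"):
        table = read_score_table(args.cohorts / f"{stem}_scores.csv")
        meta = read_metadata(args.cohorts / f"{stem}_metadata.csv")
        table = table.__class__(table.scores[PANEL], table.groups)
        filtered, excluded = filter_regions_by_missingness(table)
        probs = ratings_to_probabilities(filtered)
        event_set = build_event_set(filtered.region_names)
        model = fit_subtypes(probs, event_set, 1, fit_cfg,
                             group_label=stem)
        assignments = assign_subtype_and_stage(probs, model)
        adf = assignments_frame(assignments)
        adf.to_csv(args.out / f"{stem}_assignments.csv")
        with open(args.out / f"{stem}_model.json", "w") as fh:
            json.dump(model.to_dict(), fh)
        export_positional_variance(model, args.out / f"{stem}_positional")
        export_stage_histogram(adf, event_set.n_events + 1,
                               args.out / f"{stem}_stage_histogram")

        total = total_pathology_all(filtered)
        rows = {"total_pathology": stage_association(assignments, total)}
        for var in ("age_at_onset", "age_at_death", "disease_duration"):
            rows[var] = stage_association(assignments, meta[var])
        assoc = pd.DataFrame(rows, index=["r", "p"]).T
        assoc.to_csv(args.out / f"{stem}_associations.csv")
        print(f"{stem}: {event_set.n_events} stages over "
              f"{filtered.n_regions} regions (excluded {excluded}); "
              f"first events {model.sequences[0].tokens()[:3]}")
        print(assoc.round(3).to_string())


if __name__ == "__main__":
    main()
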