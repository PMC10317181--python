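#!/usr/bin/env python
"""Subtype discovery: CVIC model selection and region-wise contrasts.

Plants two reversed-sequence subtypes in one synthetic cohort and a
single-sequence truth in another, runs 10-fold cross-validated CVIC for
C in {1, 2} on both, fits the selected two-subtype model, assigns
subjects, screens regions with the score ~ subtype + stage GLM under
Benjamini-Hochberg correction, and checks for subtype crossover events.
Writes tables under results/subtypes/.

Run:  python analysis/03_subtype_discovery.py [--seed 1]
"""

import argparse
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from tdpstage.assignment import assign_subtype_and_stage, detect_crossover
from tdpstage.inference import FitConfig, cross_validate_cvic, fit_subtypes
from tdpstage.score_model import ratings_to_probabilities
from tdpstage.stats import regionwise_subtype_glm
from tdpstage.synthetic import (
    GeneratorConfig,
    generate_cohort,
    staircase_sequence,
    two_subtype_config,
)
from tdpstage.progression import build_event_set


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/subtypes"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    fc = FitConfig(n_starts=3, n_split_starts=2, mcmc_iterations=2000,
                   max_stored_samples=200, seed=args.seed)
    regions = tuple(f"R{i}" for i in range(8))
    es = build_event_set(regions, 3)

    # single-sequence truth: CVIC should not support a second subtype
    cfg1 = GeneratorConfig(
        region_names=regions,
        sequences=[staircase_sequence(es, regions)],
        fractions=(1.0,),
        n_subjects=200, stage_distribution="uniform", noise_epsilon=0.1,
        seed=args.seed,
    )
    probs1 = ratings_to_probabilities(generate_cohort(cfg1)[0])
    res1 = cross_validate_cvic(probs1, es, 2, fc,
                               np.random.default_rng(args.seed))
    print(f"single-sequence truth: CVIC(1)={res1.cvic[0]:.1f}, "
          f"CVIC(2)={res1.cvic[1]:.1f} -> C={res1.selected}")

    # two planted subtypes: CVIC should support both
    cfg2 = two_subtype_config(n_subjects=200, noise_epsilon=0.1,
                              seed=args.seed + 500,
                              stage_distribution="uniform")
    table2, _, truth2 = generate_cohort(cfg2)
    probs2 = ratings_to_probabilities(table2)
    res2 = cross_validate_cvic(probs2, es, 2, fc,
                               np.random.default_rng(args.seed + 500))
    print(f"two-subtype truth:     CVIC(1)={res2.cvic[0]:.1f}, "
          f"CVIC(2)={res2.cvic[1]:.1f} -> C={res2.selected}")
    pd.DataFrame({
        "C": [1, 2],
        "cvic_single_truth": res1.cvic,
        "cvic_two_subtype_truth": res2.cvic,
    }).to_csv(args.out / "cvic.csv", index=False)

    model = fit_subtypes(probs2, es, 2, fc, group_label="planted")
    assignments = assign_subtype_and_stage(probs2, model)
    pred = np.array([a.subtype for a in assignments])
    true = truth2["subtype"].to_numpy()
    acc = max((pred == true).mean(), (pred != true).mean())
    print(f"subtype assignment accuracy: {100 * acc:.1f}% "
          f"(fractions {np.round(model.fractions, 3)})")

    glm = regionwise_subtype_glm(table2, assignments)
    glm.to_csv(args.out / "regionwise_glm.csv")
    print("regions separating the subtypes (q < 0.05):",
          ", ".join(glm.index[glm["significant"]]) or "none")

    crossover = detect_crossover(assignments, 2)
    print(f"crossings of the {crossover.chance_level:.0%} chance level "
          f"after stage 1: {len(crossover.crossing_stages)} "
          f"(with near-balanced subtypes at every stage the mean subtype-1 "
          f"probability hovers at chance, so frequent crossings here mean "
          f"no stage-dominant subtype, not a discontinuity)")
    pd.DataFrame({
        "stage": crossover.stages,
        "mean_subtype1_probability": crossover.mean_subtype1_probability,
    }).to_csv(args.out / "subtype_probability_by_stage.csv", index=False)


if __name__ == "__main__":
    main()
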