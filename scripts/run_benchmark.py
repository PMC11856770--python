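#!/usr/bin/env python
"""Full benchmark protocol for users who have downloaded the benchmark cubes.

Runs the complete reference pipeline on one of the standard datasets:
band removal, per-band normalization, five repeats of (stratified split,
train 100 epochs, evaluate), and prints mean +/- sd OA/AA/Kappa with
per-class accuracies.  Expect hours of CPU time per dataset.

Example:
    python scripts/run_benchmark.py --dataset indian_pines \
        --cube Indian_pines_corrected.mat --gt Indian_pines_gt.mat
"""

from __future__ import annotations

import argparse

from sgtn.hsi_data import default_band_drops, load_cube, normalize_cube, \
    remove_bands
from sgtn.model import REFERENCE_CONFIGS, ModelConfig
from sgtn.train_eval import TrainSpec, repeat_experiment

FRACTIONS = {"indian_pines": (0.10, 0.10), "salinas": (0.01, 0.01),
             "pavia_university": (0.01, 0.01)}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dataset", required=True, choices=list(FRACTIONS))
    parser.add_argument("--cube", required=True)
    parser.add_argument("--gt", required=True)
    parser.add_argument("--epochs", type=int, default=100)
    parser.add_argument("--repeats", type=int, default=5)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--no-sga", action="store_true")
    parser.add_argument("--std-conv", action="store_true")
    args = parser.parse_args()

    cube, gt = load_cube(args.cube, args.gt)
    if args.dataset in ("indian_pines", "salinas") \
            and cube.band_count != REFERENCE_CONFIGS[args.dataset].bands:
        cube = remove_bands(cube, default_band_drops(args.dataset))
    cube = normalize_cube(cube)

    ref = REFERENCE_CONFIGS[args.dataset]
    config = ModelConfig(**{**ref.__dict__, "bands": cube.band_count,
                            "n_classes": gt.class_count,
                            "use_sga": not args.no_sga,
                            "use_msie": not args.std_conv})
    summary = repeat_experiment(cube, gt, config,
                                TrainSpec(epochs=args.epochs, seed=args.seed),
                                fractions=FRACTIONS[args.dataset],
                                n_repeats=args.repeats)
    for metric in ("oa", "aa", "kappa"):
        mean, sd = summary.mean_sd(metric)
        print(f"{metric.upper():5s} {100 * mean:6.2f} +/- {100 * sd:.2f}")
    print("\nper-class accuracy (mean +/- sd over repeats):")
    for cls, row in summary.per_class.iterrows():
        print(f"  class {cls:2d}: {100 * row['mean']:6.2f} "
              f"+/- {100 * row['sd']:.2f}")


if __name__ == "__main__":
    main()
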