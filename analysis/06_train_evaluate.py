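#!/usr/bin/env python
"""Train and evaluate the model-algorithm combinations on the canonical
screen.

Runs the median-aggregated configurations (random forest and elastic net;
classification on presence, regression on presence and colonization) with
community-grouped repeated cross-validation, evaluates on the held-out
test screen against the random-classifier and constant-mean baselines, and
writes performance and relative-importance tables.  Two of the eight seeds
are run here to keep the driver quick; the acceptance script runs all
eight for the headline numbers.
"""

import sys
import time
import warnings
from importlib import import_module
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from syncom_screen import ml

load_screen = import_module("03_preprocess_metrics").load_screen
RES = Path(__file__).resolve().parents[1] / "results"
SEEDS = ml.DEFAULT_SEEDS[:2]


def main() -> None:
    warnings.filterwarnings("ignore")
    train = load_screen("train")
    test = load_screen("test")

    perf_rows, imp_rows = [], []
    t0 = time.time()
    for cfg in ml.enumerate_configs():
        if cfg.level != "median":
            continue
        ftr = ml.build_features(train, cfg.features, cfg.level, cfg.task)
        fte = ml.build_features(test, cfg.features, cfg.level, cfg.task)
        for seed in SEEDS:
            params = ml.grouped_repeated_cv(ftr, cfg, seed=seed, n_repeats=3)
            model = ml.fit_final(ftr, cfg, params, seed=seed)
            rep = ml.evaluate_on_test(model, fte, cfg)
            for metric, value in rep.metrics.items():
                perf_rows.append((cfg.label, seed, metric, value, False))
            imp = ml.relative_importance(model, ftr, cfg, seed=seed)
            for strain, value in imp.items():
                imp_rows.append((cfg.label, seed, strain, value))
        # baselines once per config family
        if cfg.task == "classification":
            base = ml.random_classifier_baseline(ftr.y, fte.y, reps=1000, seed=SEEDS[0])
            for metric, value in base.metrics.items():
                perf_rows.append((cfg.label, SEEDS[0], metric, value, True))
        else:
            rmse0 = ml.constant_mean_baseline(ftr.y, fte.y)
            perf_rows.append((cfg.label, SEEDS[0], "rmse", rmse0, True))
        print(f"[{time.time()-t0:5.0f}s] {cfg.label}: "
              + ", ".join(f"{k}={v:.2f}" for k, v in rep.metrics.items()
                          if isinstance(v, float)))

    perf = pd.DataFrame(perf_rows, columns=["config", "seed", "metric", "value", "baseline"])
    perf.to_csv(RES / "performance.csv", index=False)
    imp = pd.DataFrame(imp_rows, columns=["config", "seed", "strain", "importance"])
    imp.to_csv(RES / "importance.csv", index=False)
    med = (imp.groupby(["strain"])["importance"].median()
              .sort_values(ascending=False))
    med.to_csv(RES / "importance_median.csv")
    print("top strains by median relative importance across analyses:")
    print(med.head(5).round(1).to_string())
    print(f"wrote performance.csv, importance.csv, importance_median.csv to {RES}")


if __name__ == "__main__":
    main()
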