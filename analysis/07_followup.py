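#!/usr/bin/env python
"""Pattern analysis after the machine learning, and validation experiments.

Splits the screened communities into "PR Strains" vs "Others", inspects
the low-colonization tail of the Others group for enriched strains, and
runs two simulated validation experiments with Bonferroni-corrected
pairwise contrasts and compact letter displays: (a) the strong strains
singly and in combination; (b) the intermediate + weak partner synergy.
"""

import sys
import warnings
from importlib import import_module
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from syncom_screen.followup import (
    split_pr_vs_others, strain_frequency_in, tail_communities, validation_contrasts,
)
from syncom_screen.ml import classification_thresholds
from syncom_screen.records import aggregate_by_box, log10_transform, normalize_pathogen
from syncom_screen.simulate import GeneratorConfig, generate_validation_experiment

load_screen = import_module("03_preprocess_metrics").load_screen
RES = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    warnings.filterwarnings("ignore")
    cfg = GeneratorConfig()
    train = load_screen("train")

    ds = normalize_pathogen(log10_transform(train), center="median")
    box = aggregate_by_box(ds).table
    box = box[box["treatment"].isin(set(train.communities.community_ids))]
    split = split_pr_vs_others(train.communities, cfg.pr_strains, box)
    split.table.to_csv(RES / "groups.csv", index=False)
    print("group medians (normalized log10):",
          {k: round(v, 2) for k, v in split.group_medians.items()})

    thr = float(np.mean(list(classification_thresholds(train).values())))
    tail = tail_communities(split, thr)
    freq = strain_frequency_in(train.communities, tail)
    freq.sort_values(ascending=False).to_csv(RES / "tail_strain_frequency.csv")
    print(f"tail of the Others group below {thr:+.2f}: {len(tail)} communities; "
          f"most frequent strains: {freq.sort_values(ascending=False).head(3).to_dict()}")

    # validation experiment 1: strong strains singly and combined
    pr = cfg.pr_strains
    tr1 = {s: frozenset({s}) for s in pr}
    tr1["pair"] = frozenset(pr[:2])
    tr1["all-PR"] = frozenset(pr)
    tr1["axenic"] = frozenset()
    vd1, _ = generate_validation_experiment(cfg, tr1, seed=11)
    res1 = validation_contrasts(vd1)
    res1.contrasts.to_csv(RES / "contrasts_pr.csv", index=False)
    print("PR validation letters:", res1.letters,
          f"(best model: {res1.model_label}, family {res1.family_size})")

    # validation experiment 2: intermediate + weak partner synergy
    tr2 = {"S04": frozenset({"S04"}), "S05": frozenset({"S05"}),
           "S04+S05": frozenset({"S04", "S05"}), "axenic": frozenset()}
    vd2, _ = generate_validation_experiment(cfg, tr2, seed=13)
    res2 = validation_contrasts(vd2)
    res2.contrasts.to_csv(RES / "contrasts_synergy.csv", index=False)
    combo = res2.contrasts.set_index("pair")
    print("synergy validation letters:", res2.letters)
    if "S04 - S04+S05" in combo.index:
        est = combo.loc["S04 - S04+S05", "estimate"]
        print(f"combination vs intermediate alone: {est:+.2f} log10 "
              f"(p_adj={combo.loc['S04 - S04+S05', 'p_bonferroni']:.3g})")
    print(f"wrote groups.csv, tail_strain_frequency.csv, contrasts_*.csv to {RES}")


if __name__ == "__main__":
    main()
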