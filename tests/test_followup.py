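"""PR-group split, tail analysis and validation contrasts with letters."""

import numpy as np
import pandas as pd
import pytest

from syncom_screen.design import CommunitySet, DesignSpec
from syncom_screen.followup import (
    compact_letter_display,
    split_pr_vs_others,
    strain_frequency_in,
    tail_communities,
    validation_contrasts,
)
from syncom_screen.records import log10_transform, normalize_pathogen, aggregate_by_box
from syncom_screen.simulate import generate_validation_experiment


def _two_communities():
    return CommunitySet(
        (frozenset("ABCDE"), frozenset("BCDEF")),
        DesignSpec(5, 6, 2), community_ids=("C1", "C2"))


def _box_medians(values):
    return pd.DataFrame({
        "box_id": [f"b{i}" for i in range(len(values))],
        "experiment": "e1",
        "treatment": [f"C{i+1}" for i in range(len(values))],
        "pathogen_median": values,
        "n_plants": 4,
    })


class TestSplit:
    def test_partition_by_membership(self):
        split = split_pr_vs_others(_two_communities(), {"A"}, _box_medians([5.0, 8.0]))
        assert split.groups == {"C1": "PR Strains", "C2": "Others"}
        assert split.group_medians["PR Strains"] == 5.0
        assert split.group_medians["Others"] == 8.0

    def test_sizes_sum_to_total(self, canonical_screen, default_config):
        train, _, _ = canonical_screen
        ds = normalize_pathogen(log10_transform(train), center="median")
        box = aggregate_by_box(ds).table
        box = box[box["treatment"].isin(set(train.communities.community_ids))]
        split = split_pr_vs_others(train.communities, default_config.pr_strains, box)
        assert len(split.groups) == 136
        assert split.group_medians["PR Strains"] < split.group_medians["Others"]

    def test_empty_pr_set_rejected(self):
        with pytest.raises(ValueError):
            split_pr_vs_others(_two_communities(), set(), _box_medians([5, 8]))


class TestTail:
    def test_empty_when_nothing_below(self):
        split = split_pr_vs_others(_two_communities(), {"A"}, _box_medians([5.0, 8.0]))
        assert tail_communities(split, threshold=7.0) == []

    def test_matches_brute_filter(self, canonical_screen, default_config):
        train, _, _ = canonical_screen
        ds = normalize_pathogen(log10_transform(train), center="median")
        box = aggregate_by_box(ds).table
        box = box[box["treatment"].isin(set(train.communities.community_ids))]
        split = split_pr_vs_others(train.communities, default_config.pr_strains, box)
        thr = -1.5
        tail = tail_communities(split, thr)
        brute = sorted(r.community_id for r in split.table.itertuples()
                       if r.group == "Others" and r.pathogen_median < thr)
        assert tail == brute

    def test_tail_enriched_for_intermediate_pair(self, canonical_screen, default_config):
        # communities escaping pathogen growth without strong strains should
        # disproportionately carry the intermediate strain
        train, _, _ = canonical_screen
        ds = normalize_pathogen(log10_transform(train), center="median")
        box = aggregate_by_box(ds).table
        box = box[box["treatment"].isin(set(train.communities.community_ids))]
        split = split_pr_vs_others(train.communities, default_config.pr_strains, box)
        tail = tail_communities(split, -1.5)
        if tail:
            freq = strain_frequency_in(train.communities, tail)
            overall = strain_frequency_in(
                train.communities,
                [c for c, g in split.groups.items() if g == "Others"])
            tail_rate = freq.get("S04", 0) / len(tail)
            base_rate = overall.get("S04", 0) / (split.table.group == "Others").sum()
            assert tail_rate > base_rate


class TestStrainFrequency:
    def test_counts_and_sum(self):
        cs = CommunitySet((frozenset("AB"), frozenset("AC")),
                          DesignSpec(2, 3, 2), community_ids=("C1", "C2"))
        freq = strain_frequency_in(cs, ["C1", "C2"])
        assert freq.to_dict() == {"A": 2, "B": 1, "C": 1}
        assert freq.sum() == 2 * 2
        assert strain_frequency_in(cs, []).empty


class TestLetters:
    def test_bonferroni_arithmetic(self):
        assert min(1.0, 0.004 * 15) == pytest.approx(0.06)

    def test_letters_iff_pairwise_significance(self):
        rng = np.random.default_rng(0)
        treatments = ["t1", "t2", "t3", "t4"]
        for _ in range(20):
            pairs = {frozenset(p) for p in
                     [("t1", "t2"), ("t1", "t3"), ("t1", "t4"),
                      ("t2", "t3"), ("t2", "t4"), ("t3", "t4")]
                     if rng.random() < 0.5}
            letters = compact_letter_display(treatments, pairs)
            for a in treatments:
                for b in treatments:
                    if a >= b:
                        continue
                    shares = bool(set(letters[a]) & set(letters[b]))
                    assert shares == (frozenset((a, b)) not in pairs)


class TestValidationContrasts:
    def test_large_effect_detected_with_distinct_letters(self):
        tr = {"S01": frozenset({"S01"}), "axenic": frozenset()}
        ds, _ = generate_validation_experiment(treatments=tr, seed=1)
        res = validation_contrasts(ds)
        row = res.contrasts.iloc[0]
        assert row["p_bonferroni"] < 0.05
        assert not set(res.letters["S01"]) & set(res.letters["axenic"])
        assert abs(row["estimate"]) == pytest.approx(2.0, abs=0.8)

    def test_identical_treatments_share_letters_mostly(self):
        shared = 0
        reps = 10
        for seed in range(reps):
            tr = {"a": frozenset({"S20"}), "b": frozenset({"S21"})}  # both neutral
            ds, _ = generate_validation_experiment(treatments=tr, seed=100 + seed)
            res = validation_contrasts(ds)
            if set(res.letters["a"]) & set(res.letters["b"]):
                shared += 1
        assert shared >= reps - 2   # ~5% nominal false-positive rate

    def test_family_size_is_declared_list_length(self):
        tr = {"S01": frozenset({"S01"}), "S04": frozenset({"S04"}), "axenic": frozenset()}
        ds, _ = generate_validation_experiment(treatments=tr, seed=2)
        res = validation_contrasts(ds, family=[("S01", "axenic"), ("S04", "axenic")])
        assert res.family_size == 2
        assert len(res.contrasts) == 2

    def test_synergy_recovered_about_one_order(self):
        tr = {"S04": frozenset({"S04"}), "S05": frozenset({"S05"}),
              "combo": frozenset({"S04", "S05"}), "axenic": frozenset()}
        ests = []
        for seed in range(5):
            ds, _ = generate_validation_experiment(treatments=tr, seed=10 + seed)
            res = validation_contrasts(ds, family=[("combo", "S04")])
            ests.append(res.contrasts["estimate"].iloc[0])
        # combo is ~1.3 orders below the intermediate alone (synergy -1 plus
        # the weak partner's own -0.3)
        assert np.mean(ests) == pytest.approx(-1.3, abs=0.45)
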