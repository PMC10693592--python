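"""Post-ML pattern analysis and validation-experiment statistics.

* Split the screened communities into a "PR Strains" group (communities
  containing at least one designated pathogen-reducing strain) and
  "Others", with per-group medians of the box medians.
* Tail analysis: Others-group communities whose median falls below a
  threshold (by default the protected/non-protected class boundary), and
  the strain frequencies within that tail.
* Validation contrasts: treatment effects in targeted follow-up
  experiments, estimated from per-box averages with the same REML model
  set / delta-AIC-4 selection as the screen association, two-sided t
  contrasts for a declared family of treatment pairs, Bonferroni
  correction, and a compact letter display (insert-and-absorb).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .association import _reml_ols
from .records import ScreenDataset, aggregate_by_box, log10_transform

__all__ = [
    "GroupSplit",
    "ContrastResult",
    "split_pr_vs_others",
    "tail_communities",
    "strain_frequency_in",
    "validation_contrasts",
    "compact_letter_display",
]


@dataclass(frozen=True)
class GroupSplit:
    pr_strain_ids: frozenset
    groups: dict[str, str]              # community_id -> 'PR Strains' | 'Others'
    group_medians: dict[str, float]     # group -> median of box medians (log10)
    table: pd.DataFrame                 # community_id, group, pathogen_median


@dataclass
class ContrastResult:
    model_label: str
    contrasts: pd.DataFrame   # pair, estimate, se, p_raw, p_bonferroni
    family_size: int
    letters: dict[str, str]
    treatment_means: dict[str, float]
    agreement: pd.DataFrame | None = None  # significance agreement across best models


def split_pr_vs_others(communities, pr_ids, box_medians: pd.DataFrame) -> GroupSplit:
    """Partition communities by presence of any designated PR strain."""
    pr = frozenset(pr_ids)
    if not pr:
        raise ValueError("pr_ids must be non-empty")
    members = communities.membership()
    med = box_medians.set_index("treatment")["pathogen_median"]
    rows = []
    groups = {}
    for cid, mem in members.items():
        g = "PR Strains" if mem & pr else "Others"
        groups[cid] = g
        if cid in med.index:
            rows.append((cid, g, float(med.loc[cid])))
    table = pd.DataFrame(rows, columns=["community_id", "group", "pathogen_median"])
    gm = {g: float(grp["pathogen_median"].median())
          for g, grp in table.groupby("group")}
    return GroupSplit(pr, groups, gm, table)


def tail_communities(split: GroupSplit, threshold: float) -> list[str]:
    """Others-group communities with median pathogen load below threshold."""
    t = split.table
    sel = t[(t["group"] == "Others") & (t["pathogen_median"] < threshold)]
    return sorted(sel["community_id"])


def strain_frequency_in(communities, community_ids) -> pd.Series:
    """Membership counts of strains over the given communities."""
    members = communities.membership()
    counts: dict[str, int] = {}
    for cid in community_ids:
        for s in members[cid]:
            counts[s] = counts.get(s, 0) + 1
    ser = pd.Series(counts, dtype=int).sort_index()
    ser.index.name = "strain_id"
    return ser


# ------------------------------------------------------- validation models


def _fit_treatment_models(box: pd.DataFrame) -> list[dict]:
    """REML fits of box-mean pathogen ~ treatment with the round lattice.

    Structures: no random effects; random intercept per experimental round;
    random round intercept plus random treatment-by-round effects (the
    random-slope analogue for a categorical fixed effect).
    """
    treatments = sorted(box["treatment"].unique())
    ref = treatments[0]
    dummies = pd.get_dummies(pd.Categorical(box["treatment"], categories=treatments),
                             drop_first=True, dtype=float)
    X = np.column_stack([np.ones(len(box)), dummies.to_numpy()])
    names = ["Intercept"] + [f"T.{t}" for t in treatments[1:]]
    y = box["value"].to_numpy(float)
    fits = []

    beta, cov, s2, llf = _reml_ols(y, X)
    fits.append({"label": "none", "beta": dict(zip(names, beta)), "cov": cov,
                 "names": names, "aic": -2 * llf + 2 * (len(names) + 1),
                 "df": len(y) - len(names), "converged": True, "ref": ref})

    for label, vc in (("round_int", None),
                      ("round_int_slope", {"tr": "0 + C(treatment)"})):
        data = box.rename(columns={"value": "y"})
        model = smf.mixedlm("y ~ C(treatment)", data, groups="experiment",
                            vc_formula=vc)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(reml=True, method="lbfgs", maxiter=200)
            except (np.linalg.LinAlgError, ValueError):
                continue
        if not (res.converged and np.isfinite(res.llf)):
            continue
        k_var = 1 + 1 + (1 if vc else 0)
        aic = -2 * float(res.llf) + 2 * (len(names) + k_var)
        fe = res.fe_params
        fe_names = list(model.exog_names)
        beta_map = {"Intercept": float(fe.iloc[0])}
        for t in treatments[1:]:
            key = [n for n in fe_names if n == f"C(treatment)[T.{t}]"]
            beta_map[f"T.{t}"] = float(fe[key[0]]) if key else 0.0
        covm = np.asarray(res.cov_params())[:len(fe_names), :len(fe_names)]
        fits.append({"label": label, "beta": beta_map, "cov": covm,
                     "names": ["Intercept"] + [f"T.{t}" for t in treatments[1:]],
                     "aic": aic, "df": len(y) - len(names),
                     "converged": True, "ref": ref})
    return fits


def _contrast(fit: dict, a: str, b: str) -> tuple[float, float]:
    """Estimate and SE of mean(a) - mean(b)."""
    names = fit["names"]
    vec = np.zeros(len(names))
    for t, sign in ((a, 1.0), (b, -1.0)):
        if t != fit["ref"]:
            vec[names.index(f"T.{t}")] += sign
    est = float(sum(vec[i] * fit["beta"][names[i]] for i in range(len(names))))
    se = float(np.sqrt(vec @ fit["cov"] @ vec))
    return est, se


def compact_letter_display(treatments: list[str],
                           significant_pairs: set[frozenset]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Treatments that share no letter differ significantly; every
    non-significant pair shares at least one letter.
    """
    sets: list[set[str]] = [set(treatments)]
    for pair in sorted(significant_pairs, key=lambda p: sorted(p)):
        a, b = sorted(pair)
        new_sets = []
        for s in sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        # absorb: drop sets contained in another
        sets = [s for s in new_sets
                if s and not any(s < t for t in new_sets if t is not s)]
        # dedupe
        uniq = []
        for s in sets:
            if s not in uniq:
                uniq.append(s)
        sets = uniq
    sets.sort(key=lambda s: sorted(s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {t: "" for t in treatments}
    for i, s in enumerate(sets):
        for t in sorted(s):
            out[t] += alphabet[i % len(alphabet)]
    return out


def validation_contrasts(dataset: ScreenDataset,
                         family: list[tuple[str, str]] | None = None,
                         alpha: float = 0.05) -> ContrastResult:
    """Treatment contrasts in a validation experiment.

    Pathogen loads are log10-transformed and averaged per microbox; the
    treatment model lattice is fitted by REML and selected by delta AIC < 4;
    contrasts come from the single best model, with significance agreement
    across the best set reported.  ``family`` defaults to all treatment
    pairs; the Bonferroni family size is exactly its length.
    """
    ds = dataset if dataset.scale == "log10" else log10_transform(dataset)
    rows = []
    boxes: dict[str, list] = {}
    for r in ds.active_records():
        boxes.setdefault(r.box_id, []).append(r)
    for box_id, recs in sorted(boxes.items()):
        rows.append((box_id, recs[0].experiment, recs[0].treatment,
                     float(np.mean([r.pathogen_cfu for r in recs]))))
    box = pd.DataFrame(rows, columns=["box_id", "experiment", "treatment", "value"])

    counts = box.groupby("treatment").size()
    singles = set(counts[counts < 2].index)
    treatments = sorted(set(box["treatment"]) - singles)
    if len(treatments) < 2:
        raise ValueError("need at least two treatments with >= 2 boxes")
    box = box[box["treatment"].isin(treatments)]
    if family is None:
        family = [(a, b) for i, a in enumerate(treatments)
                  for b in treatments[i + 1:]]
    else:
        family = [tuple(p) for p in family
                  if p[0] in treatments and p[1] in treatments]
    m = len(family)

    fits = _fit_treatment_models(box)
    amin = min(f["aic"] for f in fits)
    best_set = [f for f in fits if f["aic"] - amin < 4.0]
    best = min(best_set, key=lambda f: f["aic"])

    def _pairs_table(fit):
        recs = []
        for a, b in family:
            est, se = _contrast(fit, a, b)
            t = est / se
            p = 2.0 * stats.t.sf(abs(t), fit["df"])
            recs.append((f"{a} - {b}", a, b, est, se, p, min(1.0, p * m)))
        return pd.DataFrame(recs, columns=["pair", "a", "b", "estimate", "se",
                                           "p_raw", "p_bonferroni"])

    table = _pairs_table(best)
    sig = {frozenset((r.a, r.b)) for r in table.itertuples() if r.p_bonferroni < alpha}
    letters = compact_letter_display(treatments, sig)
    means = {}
    for t in treatments:
        means[t] = best["beta"]["Intercept"] + (
            best["beta"].get(f"T.{t}", 0.0) if t != best["ref"] else 0.0)

    agreement = None
    if len(best_set) > 1:
        cols = {}
        for f in best_set:
            tf = _pairs_table(f)
            cols[f["label"]] = (tf["p_bonferroni"] < alpha).to_numpy()
        agreement = pd.DataFrame(cols, index=table["pair"])
    return ContrastResult(best["label"], table, m, letters, means, agreement)
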