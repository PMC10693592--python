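"""Plant-level colonization records and their preprocessing.

One :class:`PlantRecord` holds the measurements of a single plant: pathogen
CFU per gram fresh weight, per-strain commensal CFU with detection and
ambiguity flags, and grouping labels (experiment, microbox, treatment).  A
:class:`ScreenDataset` is the collection for one screen together with the
community memberships.

Conventions
-----------
* CFU values are stored on the linear scale until :func:`log10_transform`
  is applied; the dataset carries a ``scale`` marker so the transform cannot
  be applied twice.
* Strains that were not detected carry the detection-floor value (never
  zero) and the flag ``below_detection``.
* Strains whose colonies could not be told apart form an ambiguity group:
  every member carries the *pooled* count and a flag ``ambiguous:<gid>``
  until :func:`partition_ambiguous` splits the pooled count equally.
* Microbox grouping is completely confounded with community composition:
  one community per box.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Literal

import numpy as np
import pandas as pd

from .design import CommunitySet

__all__ = [
    "PlantRecord",
    "ScreenDataset",
    "BoxAggregates",
    "CONTROL_TREATMENTS",
    "AXENIC_INFECTED",
    "AXENIC_NONINFECTED",
    "floor_cfu_from_dilution",
    "apply_detection_floor",
    "partition_ambiguous",
    "total_commensal",
    "log10_transform",
    "normalize_pathogen",
    "flag_outliers",
    "aggregate_by_box",
]

AXENIC_INFECTED = "axenic"
AXENIC_NONINFECTED = "axenic-NI"
FULL_POOL_CONTROL = "SynCom-35"
CONTROL_TREATMENTS = (AXENIC_NONINFECTED, AXENIC_INFECTED, FULL_POOL_CONTROL)

DETECTED = "detected"
BELOW_DETECTION = "below_detection"
AMBIGUOUS_PREFIX = "ambiguous:"


@dataclass
class PlantRecord:
    experiment: str
    box_id: str
    treatment: str
    plant_id: str
    pathogen_cfu: float
    strain_cfu: dict[str, float] = field(default_factory=dict)
    strain_flags: dict[str, str] = field(default_factory=dict)
    fresh_weight_mg: float | None = None
    outlier: bool = False
    excluded: bool = False
    exclusion_reason: str | None = None

    def ambiguity_groups(self) -> dict[str, list[str]]:
        """Map group id -> member strains, from the ambiguous flags."""
        groups: dict[str, list[str]] = {}
        for strain, flag in self.strain_flags.items():
            if flag.startswith(AMBIGUOUS_PREFIX):
                groups.setdefault(flag[len(AMBIGUOUS_PREFIX):], []).append(strain)
        for gid, members in groups.items():
            groups[gid] = sorted(members)
        return groups

    @property
    def has_ambiguous(self) -> bool:
        return any(f.startswith(AMBIGUOUS_PREFIX) for f in self.strain_flags.values())

    @property
    def has_below_detection(self) -> bool:
        return any(f == BELOW_DETECTION for f in self.strain_flags.values())


@dataclass
class ScreenDataset:
    records: list[PlantRecord]
    communities: CommunitySet | None = None
    controls: tuple[str, ...] = CONTROL_TREATMENTS
    scale: Literal["linear", "log10"] = "linear"
    normalized: bool = False

    @property
    def experiments(self) -> tuple[str, ...]:
        return tuple(sorted({r.experiment for r in self.records}))

    def copy(self) -> "ScreenDataset":
        return copy.deepcopy(self)

    def active_records(self) -> list[PlantRecord]:
        return [r for r in self.records if not r.excluded]

    def community_records(self) -> list[PlantRecord]:
        """Records of random screen communities (controls dropped)."""
        if self.communities is None:
            ids = set()
        else:
            ids = set(self.communities.community_ids)
        return [r for r in self.active_records() if r.treatment in ids]

    def exclude(self, plant_id: str, reason: str) -> None:
        """Exclude a plant for a recorded experimental reason.

        Outlier flags alone never drop a plant; exclusion needs a reason
        such as ``contamination`` or ``disturbed``.
        """
        if reason not in ("contamination", "disturbed"):
            raise ValueError(f"unknown exclusion reason: {reason!r}")
        hit = False
        for r in self.records:
            if r.plant_id == plant_id:
                r.excluded, r.exclusion_reason, hit = True, reason, True
        if not hit:
            raise KeyError(f"no record for plant {plant_id!r}")

    # ---------------------------------------------------------------- I/O

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (plant, organism) measurement."""
        rows = []
        for r in self.records:
            base = (r.experiment, r.box_id, r.treatment, r.plant_id, r.fresh_weight_mg)
            rows.append(base + ("pathogen", r.pathogen_cfu, DETECTED, r.excluded, r.exclusion_reason))
            for s in sorted(r.strain_cfu):
                rows.append(base + (s, r.strain_cfu[s], r.strain_flags.get(s, DETECTED),
                                    r.excluded, r.exclusion_reason))
        return pd.DataFrame(rows, columns=[
            "experiment", "box_id", "treatment", "plant_id", "fresh_weight_mg",
            "organism_id", "cfu_per_g", "flag", "excluded", "exclusion_reason",
        ])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, communities: CommunitySet | None = None,
                   scale: Literal["linear", "log10"] = "linear") -> "ScreenDataset":
        recs: list[PlantRecord] = []
        for (_, _, _, plant), grp in frame.groupby(
                ["experiment", "box_id", "treatment", "plant_id"], sort=True):
            first = grp.iloc[0]
            fw = first["fresh_weight_mg"]
            rec = PlantRecord(
                experiment=str(first["experiment"]), box_id=str(first["box_id"]),
                treatment=str(first["treatment"]), plant_id=str(plant),
                pathogen_cfu=math.nan, fresh_weight_mg=None if pd.isna(fw) else float(fw),
                excluded=bool(first.get("excluded", False)),
                exclusion_reason=None if pd.isna(first.get("exclusion_reason")) else str(first["exclusion_reason"]),
            )
            for _, row in grp.iterrows():
                org = str(row["organism_id"])
                if org == "pathogen":
                    rec.pathogen_cfu = float(row["cfu_per_g"])
                else:
                    rec.strain_cfu[org] = float(row["cfu_per_g"])
                    rec.strain_flags[org] = str(row["flag"])
            recs.append(rec)
        return cls(recs, communities=communities, scale=scale)

    def plants_frame(self, include_excluded: bool = False) -> pd.DataFrame:
        """Per-plant summary table (pathogen value + flags)."""
        rows = []
        for r in (self.records if include_excluded else self.active_records()):
            rows.append((r.experiment, r.box_id, r.treatment, r.plant_id,
                         r.pathogen_cfu, r.fresh_weight_mg, r.has_below_detection,
                         r.has_ambiguous, r.outlier, r.excluded))
        return pd.DataFrame(rows, columns=[
            "experiment", "box_id", "treatment", "plant_id", "pathogen",
            "fresh_weight_mg", "has_below_detection", "has_ambiguous",
            "outlier", "excluded"])


# -------------------------------------------------------------- operations


def floor_cfu_from_dilution(conversion_factor: float, count: float = 0.09) -> float:
    """Detection-floor CFU/g: a nominal count of 0.09 at the lowest counted
    dilution, converted with the same dilution-and-weight factor as a real
    count."""
    if conversion_factor <= 0:
        raise ValueError("conversion factor must be positive")
    return count * conversion_factor


def apply_detection_floor(dataset: ScreenDataset, floor_cfu: float) -> ScreenDataset:
    """Give every inoculated-but-undetected strain the floor value.

    Strains of the record's community that are missing, zero, or below the
    floor receive ``floor_cfu`` and the ``below_detection`` flag.  Detected
    strains are untouched.  Requires the linear scale.
    """
    if dataset.scale != "linear":
        raise ValueError("detection floor applies on the linear CFU scale")
    if floor_cfu <= 0:
        raise ValueError("floor must be strictly positive")
    out = dataset.copy()
    members = out.communities.membership() if out.communities is not None else {}
    for r in out.records:
        community = members.get(r.treatment, frozenset(r.strain_cfu))
        for s in sorted(community):
            v = r.strain_cfu.get(s)
            if v is None or not np.isfinite(v) or v < floor_cfu:
                if r.strain_flags.get(s, "").startswith(AMBIGUOUS_PREFIX):
                    continue  # pooled counts keep their ambiguity flag
                r.strain_cfu[s] = floor_cfu
                r.strain_flags[s] = BELOW_DETECTION
    return out


def partition_ambiguous(record: PlantRecord) -> PlantRecord:
    """Split each pooled ambiguous count equally among its group members.

    Before the split every member of a group carries the same pooled CFU
    value; afterwards each carries ``pooled / group size`` and is flagged
    ``detected``.  Total commensal CFU (each group counted once) is
    conserved exactly.
    """
    rec = copy.deepcopy(record)
    for gid, members in rec.ambiguity_groups().items():
        if len(members) < 2:
            raise ValueError(f"ambiguous group {gid!r} has fewer than 2 members")
        pooled = {rec.strain_cfu[m] for m in members}
        if len(pooled) != 1:
            raise ValueError(f"ambiguous group {gid!r} members disagree on the pooled count")
        share = pooled.pop() / len(members)
        for m in members:
            rec.strain_cfu[m] = share
            rec.strain_flags[m] = DETECTED
    return rec


def total_commensal(record: PlantRecord) -> float | None:
    """Sum of commensal CFU/g over the community strains; pathogen excluded.

    Each ambiguity group contributes its pooled count exactly once.  Returns
    ``None`` for an empty (axenic) record, as an explicit no-community
    signal.  Linear scale only.
    """
    if not record.strain_cfu:
        return None
    total = 0.0
    seen_groups: set[str] = set()
    for s, v in record.strain_cfu.items():
        flag = record.strain_flags.get(s, DETECTED)
        if flag.startswith(AMBIGUOUS_PREFIX):
            gid = flag[len(AMBIGUOUS_PREFIX):]
            if gid in seen_groups:
                continue
            seen_groups.add(gid)
        total += v
    return total


def log10_transform(dataset: ScreenDataset) -> ScreenDataset:
    """log10-transform all CFU values; guarded by the dataset scale marker."""
    if dataset.scale == "log10":
        raise ValueError("dataset already on the log10 scale")
    out = dataset.copy()
    for r in out.records:
        if r.pathogen_cfu <= 0:
            raise ValueError(f"nonpositive pathogen CFU for plant {r.plant_id}")
        r.pathogen_cfu = math.log10(r.pathogen_cfu)
        for s, v in r.strain_cfu.items():
            if v <= 0:
                raise ValueError(f"nonpositive CFU for strain {s} on plant {r.plant_id}")
            r.strain_cfu[s] = math.log10(v)
    out.scale = "log10"
    return out


def normalize_pathogen(dataset: ScreenDataset,
                       center: Literal["median", "mean"] = "median") -> ScreenDataset:
    """Center log10 pathogen values by the per-experiment axenic-infected level.

    ``center`` selects the statistic of the axenic infected controls
    (median for screen summaries, mean for the regression target).  The
    axenic controls themselves then sit near zero.
    """
    if dataset.scale != "log10":
        raise ValueError("normalize after log10 transformation")
    if dataset.normalized:
        raise ValueError("dataset already normalized")
    stat: Callable[[list[float]], float] = np.median if center == "median" else np.mean  # type: ignore[assignment]
    if center not in ("median", "mean"):
        raise ValueError("center must be 'median' or 'mean'")
    out = dataset.copy()
    for exp in out.experiments:
        ax = [r.pathogen_cfu for r in out.active_records()
              if r.experiment == exp and r.treatment == AXENIC_INFECTED]
        if not ax:
            raise ValueError(f"experiment {exp!r} has no axenic infected controls")
        c = float(stat(ax))
        for r in out.records:
            if r.experiment == exp:
                r.pathogen_cfu -= c
    out.normalized = True
    return out


def _tukey_fence(values: np.ndarray) -> tuple[float, float]:
    q1, q3 = np.quantile(values, [0.25, 0.75])  # type-7 linear interpolation
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


def flag_outliers(dataset: ScreenDataset) -> ScreenDataset:
    """Flag pathogen values outside the closed Tukey interval per treatment.

    A value is an outlier when it is not inside
    ``[Q1 - 1.5 IQR, Q3 + 1.5 IQR]`` of its treatment group (boundary values
    are kept).  Flags only — exclusion is a separate, reasoned step.
    """
    out = dataset.copy()
    groups: dict[tuple[str, str], list[PlantRecord]] = {}
    for r in out.records:
        groups.setdefault((r.experiment, r.treatment), []).append(r)
    for recs in groups.values():
        vals = np.array([r.pathogen_cfu for r in recs], dtype=float)
        lo, hi = _tukey_fence(vals)
        for r in recs:
            r.outlier = not (lo <= r.pathogen_cfu <= hi)
    return out


@dataclass(frozen=True)
class BoxAggregates:
    """Per-box medians: one row per microbox, plus per-strain medians."""

    table: pd.DataFrame          # box_id, experiment, treatment, pathogen_median, n_plants
    strain_medians: pd.DataFrame  # box_id, strain_id, cfu_median


def aggregate_by_box(dataset: ScreenDataset) -> BoxAggregates:
    """Median per microbox of the (possibly normalized) log10 values."""
    rows, srows = [], []
    boxes: dict[str, list[PlantRecord]] = {}
    for r in dataset.active_records():
        boxes.setdefault(r.box_id, []).append(r)
    if not boxes:
        raise ValueError("no active records to aggregate")
    for box_id in sorted(boxes):
        recs = boxes[box_id]
        med = float(np.median([r.pathogen_cfu for r in recs]))
        rows.append((box_id, recs[0].experiment, recs[0].treatment, med, len(recs)))
        strains = sorted({s for r in recs for s in r.strain_cfu})
        for s in strains:
            vals = [r.strain_cfu[s] for r in recs if s in r.strain_cfu]
            srows.append((box_id, s, float(np.median(vals))))
    table = pd.DataFrame(rows, columns=["box_id", "experiment", "treatment",
                                        "pathogen_median", "n_plants"])
    strain_medians = pd.DataFrame(srows, columns=["box_id", "strain_id", "cfu_median"])
    return BoxAggregates(table, strain_medians)
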