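"""Synthetic-screen generator with ground-truth bookkeeping.

The generator emulates the statistical structure of a gnotobiotic
plant-protection screen: random five-strain communities from a 35-strain
pool, one microbox of four plants per community, two training experiments
(68 communities each) plus one test experiment, axenic and full-pool
controls, log10 pathogen outcomes spanning several orders of magnitude with
a bimodal distribution driven by implanted protective strains, coupling of
the pathogen to total commensal load and community evenness, detection
floors, and ambiguous strain pairs.

The generative model for the log10 pathogen load of one plant has two
stages.  Strain-mediated suppression saturates at the residual-inoculum
floor (the sprayed pathogen dose bounds the recoverable load from below):

    S = max(mu_e + sum_s delta_s * boost + sum_pairs gamma + eps1, floor)

and the community-structure couplings then modulate the recoverable load:

    y = S + (beta_c + b_comm) * (C - C_mean)
          + (eta + h_comm) * (J - 0.5)
          + u_box + eps2

where ``C`` is the plant's total commensal log10 load, ``J`` its Pielou
evenness, ``b_comm``/``h_comm`` community-level random slopes, ``u_box`` a
box effect and ``eps1``/``eps2`` partition the plant-level residual
variance (so that for axenic controls, far above the floor,
``y ~ Normal(mu_e, residual_sd^2 + box_sd^2)`` exactly).  Axenic controls
have no strain, commensal or evenness terms.  Every random draw comes from
one seeded stream, so a config + seed reproduces the dataset exactly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .design import CommunitySet, DesignSpec, StrainPool, assemble_communities
from .metrics import StrainTree, pielou_evenness
from .records import (
    AXENIC_INFECTED,
    AXENIC_NONINFECTED,
    FULL_POOL_CONTROL,
    AMBIGUOUS_PREFIX,
    PlantRecord,
    ScreenDataset,
    apply_detection_floor,
)

__all__ = ["GeneratorConfig", "GroundTruth", "generate_screen",
           "generate_validation_experiment", "simulate_tree"]


def _default_strain_effects() -> dict[str, float]:
    # three strong pathogen-reducing strains (~2 orders of magnitude each),
    # one intermediate (~1 order) and one weak partner strain
    return {"S01": -2.0, "S02": -2.0, "S03": -2.0, "S04": -1.0, "S05": -0.3}


def _default_synergies() -> dict[frozenset, float]:
    # intermediate + weak partner act together (~1 extra order); the strong
    # strains combine additively
    return {frozenset({"S04", "S05"}): -1.0}


@dataclass(frozen=True)
class GeneratorConfig:
    """All generative-model parameters; defaults are the study conditions."""

    pool_size: int = 35
    community_size: int = 5
    n_train_communities: int = 136      # split over 2 experiments
    n_test_communities: int = 70        # 68 random + SynCom-Low + SynCom-High
    plants_per_box: int = 4
    axenic_mean: float = 8.5            # log10 CFU/g of axenic infected plants
    box_sd: float = 0.3
    residual_sd: float = 1.0
    strain_effects: dict[str, float] = field(default_factory=_default_strain_effects)
    synergy_effects: dict[frozenset, float] = field(default_factory=_default_synergies)
    commensal_slope: float = 1.4
    commensal_slope_sd: float = 0.6
    commensal_mean: float = 8.0
    commensal_sd: float = 0.4
    evenness_effect: float = -1.3
    evenness_effect_sd: float = 2.2
    # protective effects strengthen with neutral co-members (community context);
    # zero for the single-strain and strain-pair validation treatments
    context_boost: float = 0.06
    dirichlet_alpha: float = 0.3
    detection_floor_log10: float = 3.5
    pathogen_floor_log10: float = 4.2   # residual inoculum: loads cannot fall below it
    pathogen_floor_sd: float = 0.5
    # fraction of the residual SD acting inside the saturation stage
    suppression_noise_fraction: float = 0.8
    ambiguity_rate: float = 0.16
    n_axenic_boxes_train: int = 7
    n_axenic_boxes_test: int = 9
    n_axenic_ni_boxes: int = 2
    weight_mean_mg: float = 40.0
    weight_sd_mg: float = 12.0

    def __post_init__(self) -> None:
        for name in ("box_sd", "residual_sd", "commensal_slope_sd", "commensal_sd",
                     "evenness_effect_sd", "weight_sd_mg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.ambiguity_rate <= 1:
            raise ValueError("ambiguity_rate must be in [0, 1]")
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be positive")
        pool = set(StrainPool.numbered(self.pool_size).strain_ids)
        missing = set(self.strain_effects) - pool
        if missing:
            raise ValueError(f"effect strains not in pool: {sorted(missing)}")

    @property
    def pool(self) -> StrainPool:
        return StrainPool.numbered(self.pool_size)

    @property
    def pr_strains(self) -> tuple[str, ...]:
        """Strains with a strong (<= -1.5 log10) individual effect."""
        return tuple(sorted(s for s, d in self.strain_effects.items() if d <= -1.5))

    def null(self) -> "GeneratorConfig":
        """Copy with every coupling and strain effect set to zero."""
        return dataclasses.replace(
            self, strain_effects={}, synergy_effects={},
            commensal_slope=0.0, commensal_slope_sd=0.0,
            evenness_effect=0.0, evenness_effect_sd=0.0)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["synergy_effects"] = {"+".join(sorted(k)): v
                                for k, v in self.synergy_effects.items()}
        return json.dumps(d, indent=1, sort_keys=True)


@dataclass
class GroundTruth:
    """Generator-internal truth for recovery tests."""

    config: GeneratorConfig
    seed: int
    community_effects: dict[str, dict]   # community_id -> mu, b_comm, h_comm, members
    box_effects: dict[str, float]        # box_id -> u_box
    tree_newick: str

    def expected_log10(self, community_id: str) -> float:
        """Expected log10 pathogen load of a community at average commensal
        load and J = 0.5, excluding box and plant noise."""
        return self.community_effects[community_id]["mu"]


def simulate_tree(pool: StrainPool, seed: int = 0) -> StrainTree:
    """Random binary tree over the pool with exponential branch lengths.

    Built by random sequential joins (a coalescent-style topology);
    deterministic per seed.
    """
    if pool.size < 3:
        raise ValueError("need at least 3 strains for a tree")
    rng = np.random.default_rng(seed)
    nodes = [f"{s}:{rng.exponential(0.1):.6f}" for s in pool.strain_ids]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        merged = f"({a},{b}):{rng.exponential(0.1):.6f}"
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)] + [merged]
    newick = f"({nodes[0]},{nodes[1]});"
    return StrainTree.from_newick(newick)


def _community_sum(cfg: GeneratorConfig, members: frozenset) -> float:
    """Summed strain and synergy effects of one community.

    Each effect strain's contribution is amplified by its neutral
    co-members, ``delta * (1 + context_boost * n_neutral)``; pairwise
    synergies enter unamplified.
    """
    n_neutral = sum(1 for s in members if cfg.strain_effects.get(s, 0.0) == 0.0)
    boost = 1.0 + cfg.context_boost * n_neutral
    total = sum(cfg.strain_effects.get(s, 0.0) for s in members) * boost
    for pair, g in cfg.synergy_effects.items():
        if pair <= members:
            total += g
    return total


class _Generator:
    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.truth_comm: dict[str, dict] = {}
        self.truth_box: dict[str, float] = {}

    def community_draws(self, cid: str, members: frozenset) -> dict:
        cfg = self.cfg
        eff = {
            "members": sorted(members),
            "strain_sum": _community_sum(cfg, members),
            "b_comm": float(self.rng.normal(0.0, cfg.commensal_slope_sd)),
            "h_comm": float(self.rng.normal(0.0, cfg.evenness_effect_sd)),
        }
        eff["mu"] = cfg.axenic_mean + eff["strain_sum"]
        self.truth_comm[cid] = eff
        return eff

    def make_box(self, experiment: str, box_id: str, treatment: str,
                 members: frozenset | None) -> list[PlantRecord]:
        cfg, rng = self.cfg, self.rng
        u_box = float(rng.normal(0.0, cfg.box_sd))
        self.truth_box[box_id] = u_box
        eff = self.truth_comm.get(treatment)
        if members and eff is None:
            eff = self.community_draws(treatment, members)
        f1 = cfg.suppression_noise_fraction
        f2 = math.sqrt(max(0.0, 1.0 - f1 * f1))
        records = []
        for p in range(1, cfg.plants_per_box + 1):
            eps1 = float(rng.normal(0.0, cfg.residual_sd * f1))
            eps2 = float(rng.normal(0.0, cfg.residual_sd * f2))
            floor = float(rng.normal(cfg.pathogen_floor_log10, cfg.pathogen_floor_sd))
            weight = max(5.0, float(rng.normal(cfg.weight_mean_mg, cfg.weight_sd_mg)))
            strain_cfu: dict[str, float] = {}
            strain_flags: dict[str, str] = {}
            if members:
                c_log = float(rng.normal(cfg.commensal_mean, cfg.commensal_sd))
                shares = rng.dirichlet(np.full(len(members), cfg.dirichlet_alpha))
                j = pielou_evenness(shares) if len(members) >= 2 else None
                # saturation stage: suppression cannot push the load below
                # the residual inoculum
                s_level = max(eff["mu"] + eps1, floor)
                y = (s_level
                     + (cfg.commensal_slope + eff["b_comm"]) * (c_log - cfg.commensal_mean)
                     + ((cfg.evenness_effect + eff["h_comm"]) * (j - 0.5) if j is not None else 0.0)
                     + u_box + eps2)
                total = 10.0 ** c_log
                for s, share in zip(sorted(members), shares):
                    strain_cfu[s] = share * total
                    strain_flags[s] = "detected"
            else:
                y = max(cfg.axenic_mean + eps1, floor) + u_box + eps2
            if treatment == AXENIC_NONINFECTED:
                pathogen = 10.0 ** 2.0  # below any meaningful load; excluded from analyses
            else:
                pathogen = 10.0 ** y
            records.append(PlantRecord(
                experiment=experiment, box_id=box_id, treatment=treatment,
                plant_id=f"{box_id}-p{p}", pathogen_cfu=pathogen,
                strain_cfu=strain_cfu, strain_flags=strain_flags,
                fresh_weight_mg=weight))
        return records

    def add_ambiguity(self, records: list[PlantRecord]) -> None:
        """Pool the counts of one random strain pair on a fraction of plants."""
        cfg, rng = self.cfg, self.rng
        for r in records:
            eligible = [s for s, f in r.strain_flags.items() if f == "detected"]
            if len(eligible) >= 2 and rng.random() < cfg.ambiguity_rate:
                pair = rng.choice(len(eligible), size=2, replace=False)
                a, b = eligible[pair[0]], eligible[pair[1]]
                pooled = r.strain_cfu[a] + r.strain_cfu[b]
                gid = "g1"
                for s in (a, b):
                    r.strain_cfu[s] = pooled
                    r.strain_flags[s] = AMBIGUOUS_PREFIX + gid


def _finalize(cfg: GeneratorConfig, records: list[PlantRecord],
              communities: CommunitySet | None, gen: _Generator) -> ScreenDataset:
    ds = ScreenDataset(records, communities=communities)
    gen.add_ambiguity(ds.records)
    ds = apply_detection_floor(ds, 10.0 ** cfg.detection_floor_log10)
    return ds


def generate_screen(cfg: GeneratorConfig | None = None, seed: int = 0
                    ) -> tuple[ScreenDataset, ScreenDataset, GroundTruth]:
    """Generate the training screen (two experiments), the test screen and
    the ground truth.

    Training communities are unique; test compositions are additionally
    disjoint from the training ones.  Each experiment carries axenic
    infected, axenic non-infected and full-pool control boxes; the test
    experiment additionally contains the two fixed control communities
    SynCom-Low (protective) and SynCom-High (non-protective).
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(seed)
    pool = cfg.pool
    k = cfg.community_size

    low = frozenset(sorted(cfg.strain_effects)[:k]) if len(cfg.strain_effects) >= 2 \
        else frozenset(pool.strain_ids[:k])
    high = frozenset(pool.strain_ids[-k:])
    reserved = {low, high}

    n_train, n_test_random = cfg.n_train_communities, cfg.n_test_communities - 2
    spec_all = DesignSpec(k=k, n=cfg.pool_size, N=n_train + n_test_random)
    # one oversized draw, then reject reserved compositions, keeps everything unique
    seed_assemble = int(rng.integers(0, 2**31 - 1))
    cs_all = assemble_communities(pool, dataclasses.replace(spec_all, N=spec_all.N + 4),
                                  seed=seed_assemble, enforce_unique=True)
    comms = [c for c in cs_all.communities if c not in reserved][: spec_all.N]
    train_cs = CommunitySet(tuple(comms[:n_train]),
                            DesignSpec(k=k, n=cfg.pool_size, N=n_train))
    test_comms = tuple(comms[n_train:]) + (low, high)
    test_ids = tuple(f"T{i:03d}" for i in range(1, n_test_random + 1)) + (
        "SynCom-Low", "SynCom-High")
    test_cs = CommunitySet(test_comms, DesignSpec(k=k, n=cfg.pool_size, N=cfg.n_test_communities),
                           community_ids=test_ids)

    tree = simulate_tree(pool, seed=int(rng.integers(0, 2**31 - 1)))
    gen = _Generator(cfg, rng)
    full_pool = frozenset(pool.strain_ids)

    train_records: list[PlantRecord] = []
    half = n_train // 2
    train_members = train_cs.membership()
    for e, ids in enumerate((train_cs.community_ids[:half], train_cs.community_ids[half:]), 1):
        exp = f"exp{e}"
        for cid in ids:
            train_records += gen.make_box(exp, f"{exp}-{cid}", cid, train_members[cid])
        train_records += gen.make_box(exp, f"{exp}-syn35", FULL_POOL_CONTROL, full_pool)
        for b in range(1, cfg.n_axenic_boxes_train + 1):
            train_records += gen.make_box(exp, f"{exp}-ax{b}", AXENIC_INFECTED, None)
        for b in range(1, cfg.n_axenic_ni_boxes + 1):
            train_records += gen.make_box(exp, f"{exp}-axNI{b}", AXENIC_NONINFECTED, None)

    exp = "exp3"
    test_records: list[PlantRecord] = []
    test_members = test_cs.membership()
    for cid in test_cs.community_ids:
        test_records += gen.make_box(exp, f"{exp}-{cid}", cid, test_members[cid])
    test_records += gen.make_box(exp, f"{exp}-syn35", FULL_POOL_CONTROL, full_pool)
    for b in range(1, cfg.n_axenic_boxes_test + 1):
        test_records += gen.make_box(exp, f"{exp}-ax{b}", AXENIC_INFECTED, None)
    for b in range(1, cfg.n_axenic_ni_boxes + 1):
        test_records += gen.make_box(exp, f"{exp}-axNI{b}", AXENIC_NONINFECTED, None)

    train = _finalize(cfg, train_records, train_cs, gen)
    test = _finalize(cfg, test_records, test_cs, gen)
    truth = GroundTruth(config=cfg, seed=seed, community_effects=gen.truth_comm,
                        box_effects=gen.truth_box, tree_newick=tree.as_newick())
    return train, test, truth


def generate_validation_experiment(
        cfg: GeneratorConfig | None = None,
        treatments: dict[str, frozenset] | None = None,
        n_boxes_per_treatment: int = 6,
        seed: int = 0) -> tuple[ScreenDataset, GroundTruth]:
    """Targeted follow-up experiment: arbitrary strain sets (singletons,
    pairs, quads, controls) inoculated on ``n_boxes_per_treatment`` boxes of
    four plants, split over two experimental rounds.

    ``treatments`` maps treatment label to a (possibly empty) strain set;
    an empty set is an axenic infected treatment.  The same generative
    model applies; single-strain treatments have no evenness term.
    """
    cfg = cfg or GeneratorConfig()
    if treatments is None:
        pr = cfg.pr_strains
        treatments = {s: frozenset({s}) for s in pr}
        treatments["pair"] = frozenset(pr[:2])
        treatments[AXENIC_INFECTED] = frozenset()
    for name, members in treatments.items():
        unknown = set(members) - set(cfg.pool.strain_ids)
        if unknown:
            raise ValueError(f"treatment {name!r} uses unknown strains {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    gen = _Generator(cfg, rng)
    records: list[PlantRecord] = []
    per_round = max(1, n_boxes_per_treatment // 2)
    for b in range(1, n_boxes_per_treatment + 1):
        rnd = "round1" if b <= per_round else "round2"
        for name, members in treatments.items():
            safe = name.replace(" ", "_")
            records += gen.make_box(rnd, f"{rnd}-{safe}-b{b}", name, members or None)
    ds = _finalize(cfg, records, None, gen)
    truth = GroundTruth(config=cfg, seed=seed, community_effects=gen.truth_comm,
                        box_effects=gen.truth_box, tree_newick="")
    return ds, truth
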