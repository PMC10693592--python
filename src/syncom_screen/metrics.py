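"""Community-structure metrics on an unrooted strain phylogeny.

Three metrics describe a community's structure at the end of the assay:

* Pielou evenness ``J = H' / ln(S)`` of the relative strain abundances,
* Faith's phylogenetic diversity (sum of branch lengths of the minimal
  unrooted subtree spanning the members), computed from inoculum
  *presence*, and
* abundance-weighted mean pairwise (patristic) distance,
  ``sum_{i<j} w_i w_j d_ij / sum_{i<j} w_i w_j``.

All three are defined for unrooted trees with branch lengths; any root in
the input newick is ignored for distance purposes.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "StrainTree",
    "pielou_evenness",
    "faith_pd",
    "weighted_mpd",
    "compute_all",
]


class StrainTree:
    """Phylogeny of the strain pool; wraps a dendropy tree.

    Leaf labels are strain ids; branch lengths must be non-negative.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self.leaf_labels = frozenset(l.taxon.label for l in tree.leaf_node_iter())
        for e in tree.preorder_edge_iter():
            if e.length is not None and e.length < 0:
                raise ValueError("negative branch length in strain tree")
        pdm = tree.phylogenetic_distance_matrix()
        labels = sorted(self.leaf_labels)
        self._index = {s: i for i, s in enumerate(labels)}
        n = len(labels)
        d = np.zeros((n, n))
        taxa = {t.label: t for t in tree.taxon_namespace if t.label in self.leaf_labels}
        for i, a in enumerate(labels):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.patristic_distance(taxa[a], taxa[labels[j]])
        self._dist = d

    @classmethod
    def from_newick(cls, source: str) -> "StrainTree":
        """Read from a newick string or file path."""
        if "(" in source:
            tree = dendropy.Tree.get(data=source, schema="newick")
        else:
            tree = dendropy.Tree.get(path=source, schema="newick")
        return cls(tree)

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick")

    def patristic_distance(self, a: str, b: str) -> float:
        self._check_members([a, b])
        return float(self._dist[self._index[a], self._index[b]])

    def distance_matrix(self) -> pd.DataFrame:
        labels = sorted(self.leaf_labels)
        return pd.DataFrame(self._dist, index=labels, columns=labels)

    def _check_members(self, members: Iterable[str]) -> list[str]:
        members = sorted(set(members))
        unknown = [m for m in members if m not in self.leaf_labels]
        if unknown:
            raise KeyError(f"strains not in tree: {unknown}")
        return members


def pielou_evenness(abundances: Mapping[str, float] | Iterable[float],
                    fixed_richness: int | None = None) -> float | None:
    """Pielou's evenness J of a community's relative abundances.

    ``J = H' / ln(S)`` with ``H' = -sum p_i ln p_i`` over the ``S`` strains
    with positive abundance (or ``S = fixed_richness`` to use the inoculated
    richness instead).  Invariant to rescaling.  Returns ``None`` when fewer
    than two strains have positive abundance (evenness undefined).
    """
    vals = np.asarray(list(abundances.values()) if isinstance(abundances, Mapping)
                      else list(abundances), dtype=float)
    if np.any(vals < 0):
        raise ValueError("abundances must be non-negative")
    pos = vals[vals > 0]
    s = len(pos) if fixed_richness is None else int(fixed_richness)
    if len(pos) < 2 or s < 2:
        return None
    p = pos / pos.sum()
    h = -float(np.sum(p * np.log(p)))
    return h / log(s)


def faith_pd(tree: StrainTree, members: Iterable[str]) -> float:
    """Faith's PD: total branch length of the minimal unrooted subtree
    spanning ``members``.

    An edge belongs to the spanning subtree iff removing it separates at
    least one member from another; monotone non-decreasing when members are
    added.  Requires at least two members.
    """
    members = tree._check_members(members)
    if len(members) < 2:
        raise ValueError("Faith PD needs at least two members")
    mset = set(members)
    total_in = 0
    pd_sum = 0.0
    counts: dict[int, int] = {}
    t = tree._tree
    for node in t.postorder_node_iter():
        if node.is_leaf():
            c = 1 if node.taxon.label in mset else 0
        else:
            c = sum(counts[id(ch)] for ch in node.child_nodes())
        counts[id(node)] = c
        if node.parent_node is not None and node.edge.length:
            total_in = len(mset)
            if 0 < c < total_in:
                pd_sum += node.edge.length
    return pd_sum


def weighted_mpd(tree: StrainTree, abundances: Mapping[str, float]) -> float | None:
    """Abundance-weighted mean pairwise patristic distance.

    ``sum_{i<j} w_i w_j d_ij / sum_{i<j} w_i w_j`` over unordered pairs of
    distinct strains with positive abundance (self-pairs excluded), with
    ``w`` the relative abundances.  Returns ``None`` for communities with
    fewer than two positive strains.
    """
    items = [(s, a) for s, a in abundances.items() if a > 0]
    if any(a < 0 for a in abundances.values()):
        raise ValueError("abundances must be non-negative")
    if len(items) < 2:
        return None
    labels = tree._check_members(s for s, _ in items)
    w = np.array([dict(items)[s] for s in labels], dtype=float)
    w = w / w.sum()
    idx = [tree._index[s] for s in labels]
    d = tree._dist[np.ix_(idx, idx)]
    outer = np.outer(w, w)
    iu = np.triu_indices(len(labels), k=1)
    return float(np.sum(outer[iu] * d[iu]) / np.sum(outer[iu]))


@dataclass(frozen=True)
class _CommunityAbundances:
    community_id: str
    abundances: dict[str, float]
    members: frozenset[str]
    n_detected: int
    has_below_detection: bool
    has_ambiguous: bool


def compute_all(dataset, tree: StrainTree, mode: str = "realized",
                fixed_richness: int | None = None) -> pd.DataFrame:
    """Per-community metrics table.

    ``mode='inoculum'`` uses presence only (Faith PD from the inoculated
    membership); ``mode='realized'`` additionally computes evenness and
    weighted mpd from end-point abundances (per-strain medians across the
    community's plants, ambiguous counts partitioned equally).  Failures
    are recorded per community (NaN + flags), never fatal for the batch.
    """
    from .records import aggregate_by_box, partition_ambiguous

    if mode not in ("inoculum", "realized"):
        raise ValueError("mode must be 'inoculum' or 'realized'")
    if dataset.communities is None:
        raise ValueError("dataset has no community set")
    if dataset.scale != "linear":
        raise ValueError("compute metrics on the linear CFU scale")
    members = dataset.communities.membership()

    comms: dict[str, _CommunityAbundances] = {}
    per_comm: dict[str, list] = {}
    for r in dataset.community_records():
        per_comm.setdefault(r.treatment, []).append(r)
    for cid, recs in sorted(per_comm.items()):
        parts = [partition_ambiguous(r) for r in recs]
        strains = sorted(members[cid])
        ab = {s: float(np.median([p.strain_cfu.get(s, 0.0) for p in parts]))
              for s in strains}
        detected = {s for r in recs for s, f in r.strain_flags.items()
                    if not f.startswith(("below_detection",))}
        comms[cid] = _CommunityAbundances(
            cid, ab, members[cid], len(detected & set(strains)),
            any(r.has_below_detection for r in recs),
            any(r.has_ambiguous for r in recs))

    rows = []
    for cid, ca in comms.items():
        even = w_mpd = fpd = np.nan
        n_detected = ca.n_detected
        try:
            fpd = faith_pd(tree, ca.members)
        except (KeyError, ValueError):
            pass
        if mode == "realized":
            j = pielou_evenness(ca.abundances, fixed_richness=fixed_richness)
            even = np.nan if j is None else j
            m = weighted_mpd(tree, ca.abundances)
            w_mpd = np.nan if m is None else m
        rows.append((cid, even, fpd, w_mpd, n_detected,
                     ca.has_below_detection, ca.has_ambiguous))
    return pd.DataFrame(rows, columns=[
        "community_id", "evenness", "faith_pd", "weighted_mpd",
        "n_detected", "has_below_detection", "has_ambiguous"])
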