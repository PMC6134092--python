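"""Clade-level aggregation: the clade-based taxonomic unit core.

Every internal node of the OTU phylogeny (the root included) is a
clade-based taxonomic unit.  Its abundance in a sample is the sum of
the counts of its member tips, computed in a single post-order pass;
presence is abundance >= a detection threshold (1 count by default),
and prevalence over a sample set is the number of samples where the
clade is present.  A clade's taxonomy label is the most granular
rank-prefixed lineage shared exactly by all of its member tips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import EcocladeError
from .tree import PhyloTree

__all__ = [
    "CladeProfile",
    "compute_clade_profile",
    "clade_prevalence",
    "label_clade_taxonomy",
]

UNCLASSIFIED = "Unclassified"


@dataclass
class CladeProfile:
    """Clade x sample abundance/presence matrices plus membership.

    ``tip_presence`` is the tip-level binary matrix the permutation
    null operates on (tip count >= presence_threshold).
    """

    tree: PhyloTree
    abundance: pd.DataFrame           # clades x samples
    presence: pd.DataFrame            # clades x samples, 0/1
    tip_presence: pd.DataFrame        # tips x samples, 0/1
    presence_threshold: float = 1.0

    @property
    def clade_ids(self) -> list:
        return list(self.abundance.index)

    @property
    def sample_ids(self) -> list:
        return list(self.abundance.columns)

    def membership(self, clade_id: str) -> Tuple[str, ...]:
        return self.tree.clade_tips(clade_id)

    def membership_matrix(self) -> np.ndarray:
        """Boolean clades x tips matrix in canonical order."""
        tips = self.tree.tip_labels
        tip_idx = {t: i for i, t in enumerate(tips)}
        M = np.zeros((len(self.clade_ids), len(tips)), dtype=bool)
        for ci, cid in enumerate(self.clade_ids):
            for t in self.tree.clade_tips(cid):
                M[ci, tip_idx[t]] = True
        return M


def compute_clade_profile(
    tree: PhyloTree,
    table: pd.DataFrame,
    presence_threshold: float = 1.0,
) -> CladeProfile:
    """Aggregate a tip x sample count table over every clade of the tree.

    ``tree`` and ``table`` must cover the same OTU universe (use
    :func:`ecoclade.community.align_tree_table` first).
    """
    if set(tree.tip_labels) != set(table.index):
        raise EcocladeError(
            "tree tips and table rows differ; align tree and table first"
        )
    counts = table.loc[tree.tip_labels]
    samples = list(table.columns)
    values = counts.to_numpy(dtype=float)
    tip_idx = {t: i for i, t in enumerate(tree.tip_labels)}

    # post-order accumulation: child sums propagate upward
    sums: Dict[str, np.ndarray] = {}

    def post(node_id: str) -> np.ndarray:
        children = tree.children_ids(node_id)
        if not children:
            return values[tip_idx[node_id]]
        total = np.zeros(len(samples))
        for c in children:
            total = total + post(c)
        sums[node_id] = total
        return total

    post(tree.root_id)
    abundance = pd.DataFrame(
        [sums[cid] for cid in tree.clade_ids],
        index=pd.Index(tree.clade_ids, name="clade_id"),
        columns=samples,
    )
    presence = (abundance >= presence_threshold).astype(np.int8)
    tip_presence = (counts >= presence_threshold).astype(np.int8)
    return CladeProfile(
        tree=tree,
        abundance=abundance,
        presence=presence,
        tip_presence=tip_presence,
        presence_threshold=presence_threshold,
    )


def clade_prevalence(
    profile: CladeProfile, clade_id: str, samples: Optional[Iterable[str]] = None
) -> int:
    """Number of samples (of a subset) where the clade is present."""
    if clade_id not in profile.presence.index:
        raise EcocladeError(f"unknown clade id: {clade_id!r}")
    cols = list(samples) if samples is not None else profile.sample_ids
    if not cols:
        raise EcocladeError("empty sample subset")
    missing = [s for s in cols if s not in profile.presence.columns]
    if missing:
        raise EcocladeError(f"unknown samples: {', '.join(missing)}")
    return int(profile.presence.loc[clade_id, cols].sum())


def _split_lineage(lineage: str) -> list:
    return [part.strip() for part in lineage.split(";") if part.strip() != ""]


def label_clade_taxonomy(
    profile: CladeProfile, clade_id: str, taxonomy: Mapping[str, str]
) -> str:
    """Most granular lineage shared exactly by all member tips.

    Ranks agree only on exact string equality (an empty payload such as
    ``g__`` matches only another ``g__``).  Tips without a taxonomy
    entry contribute no agreement, so any such tip yields
    ``"Unclassified"``; so does an empty shared prefix.
    """
    tips = profile.membership(clade_id)
    lineages = []
    for t in tips:
        if t not in taxonomy:
            return UNCLASSIFIED
        lineages.append(_split_lineage(taxonomy[t]))
    if not lineages:
        return UNCLASSIFIED
    shared = []
    for ranks in zip(*lineages):
        if all(r == ranks[0] for r in ranks):
            shared.append(ranks[0])
        else:
            break
    return ";".join(shared) if shared else UNCLASSIFIED


def clade_annotation(
    profile: CladeProfile, taxonomy: Optional[Mapping[str, str]] = None
) -> pd.DataFrame:
    """Per-clade annotation table: n_tips and taxonomy label."""
    rows = []
    for cid in profile.clade_ids:
        label = (
            label_clade_taxonomy(profile, cid, taxonomy)
            if taxonomy is not None
            else UNCLASSIFIED
        )
        rows.append({"clade_id": cid,
                     "n_tips": len(profile.membership(cid)),
                     "taxonomy_label": label})
    return pd.DataFrame(rows).set_index("clade_id")
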