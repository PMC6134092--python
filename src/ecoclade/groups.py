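"""Cross-group clade classification.

Given per-group conservation scans over a common clade universe, the
operations here separate:

* **exclusive** clades — detected in at least one sample of a group and
  in no sample outside it (exclusivity is relative to the samples of
  the invocation, not to all conceivable hosts);
* **uniquely conserved** clades — conserved in exactly one of the
  tested groups, though possibly present elsewhere;
* the **overlap table** — for every combination of groups, the number
  of clades conserved in exactly that combination (the long-format
  equivalent of a Venn diagram over conserved clades).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Set, Union

import pandas as pd

from .errors import EcocladeError
from .profile import CladeProfile

__all__ = ["GroupCladeSets", "find_exclusive", "classify_groups",
           "occurrence_matrix"]


@dataclass
class GroupCladeSets:
    groups: List[str]
    conserved: Dict[str, Set[str]]
    exclusive: Dict[str, Set[str]]
    uniquely_conserved: Dict[str, Set[str]]
    overlap: Dict[FrozenSet[str], int]

    def overlap_frame(self) -> pd.DataFrame:
        rows = [
            {"groups": "+".join(sorted(combo)), "n_groups": len(combo),
             "n_clades": count}
            for combo, count in sorted(
                self.overlap.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
            )
        ]
        return pd.DataFrame(rows, columns=["groups", "n_groups", "n_clades"])

    def sets_frame(self) -> pd.DataFrame:
        all_clades = sorted(set().union(*self.conserved.values(), *self.exclusive.values())
                            if self.conserved or self.exclusive else set())
        rows = []
        for clade in all_clades:
            for g in self.groups:
                rows.append({
                    "clade_id": clade,
                    "group": g,
                    "conserved": clade in self.conserved[g],
                    "exclusive": clade in self.exclusive[g],
                    "uniquely_conserved": clade in self.uniquely_conserved[g],
                })
        return pd.DataFrame(rows,
                            columns=["clade_id", "group", "conserved",
                                     "exclusive", "uniquely_conserved"])


def _group_samples(profile: CladeProfile, metadata: pd.DataFrame,
                   group_column: str, group_value: str) -> List[str]:
    if group_column not in metadata.columns:
        raise EcocladeError(f"unknown group column {group_column!r}")
    col = metadata[group_column]
    return [s for s in profile.sample_ids
            if s in metadata.index and col.loc[s] == group_value]


def find_exclusive(
    profile: CladeProfile,
    metadata: pd.DataFrame,
    group_column: str,
    group_value: str,
) -> Set[str]:
    """Clades present in >= 1 group sample and absent from all others."""
    inside = _group_samples(profile, metadata, group_column, group_value)
    if not inside:
        raise EcocladeError(f"no samples in group {group_value!r}")
    outside = [s for s in profile.sample_ids if s not in set(inside)]
    if not outside:
        raise EcocladeError(
            "exclusivity is undefined without samples outside the group"
        )
    pres = profile.presence
    mask = (pres[inside].sum(axis=1) > 0) & (pres[outside].sum(axis=1) == 0)
    return set(pres.index[mask])


def classify_groups(
    results: Union[Mapping[str, pd.DataFrame], pd.DataFrame],
    profile: CladeProfile,
    metadata: pd.DataFrame,
    group_column: str,
) -> GroupCladeSets:
    """Combine per-group conservation scans into group-level clade sets.

    ``results`` is either a mapping group -> scan table or one
    concatenated table with a ``group`` column.  All scans must share
    the clade universe of ``profile``.
    """
    if isinstance(results, pd.DataFrame):
        results = {g: df for g, df in results.groupby("group", sort=False)}
    results = dict(results)
    if len(results) < 2:
        raise EcocladeError("classification needs results for >= 2 groups")
    universe = set(profile.clade_ids)
    for g, df in results.items():
        if set(df["clade_id"]) != universe:
            raise EcocladeError(
                f"result table for group {g!r} does not match the clade "
                "universe of the profile"
            )
    groups = list(results)
    conserved = {
        g: set(df.loc[df["conserved"].astype(bool), "clade_id"])
        for g, df in results.items()
    }
    exclusive = {
        g: find_exclusive(profile, metadata, group_column, g) for g in groups
    }
    uniquely = {
        g: {c for c in conserved[g]
            if not any(c in conserved[h] for h in groups if h != g)}
        for g in groups
    }
    union = set().union(*conserved.values())
    overlap: Dict[FrozenSet[str], int] = {}
    for clade in union:
        combo = frozenset(g for g in groups if clade in conserved[g])
        overlap[combo] = overlap.get(combo, 0) + 1
    return GroupCladeSets(
        groups=groups, conserved=conserved, exclusive=exclusive,
        uniquely_conserved=uniquely, overlap=overlap,
    )


def occurrence_matrix(
    profile: CladeProfile,
    clades: Iterable[str],
    metadata: Optional[pd.DataFrame] = None,
    order_by: Union[None, str, List[str]] = None,
) -> pd.DataFrame:
    """Samples x clades binary occurrence matrix.

    ``order_by`` orders the sample rows: a metadata column name (stable
    sort by its values) or an explicit sample-id list.
    """
    clades = list(clades)
    unknown = [c for c in clades if c not in profile.presence.index]
    if unknown:
        raise EcocladeError(f"unknown clades: {', '.join(unknown)}")
    mat = profile.presence.loc[clades].T
    if isinstance(order_by, str):
        if metadata is None or order_by not in metadata.columns:
            raise EcocladeError(f"unknown ordering column {order_by!r}")
        order = metadata.loc[[s for s in mat.index if s in metadata.index]]
        order = order.sort_values(order_by, kind="stable")
        mat = mat.loc[order.index]
    elif order_by is not None:
        mat = mat.loc[list(order_by)]
    mat.index.name = "sample_id"
    return mat
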