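"""Gain/loss imputation of clade conservation on a host phylogeny.

Each character is one clade's conservation status (0/1) across host
groups, which are the tips of a (small, group-level) host tree.  The
tree is rooted on the out-group's edge and ancestral states are
reconstructed by Fitch parsimony: an intersection/union down-pass
followed by an up-pass in which the root is clamped to the out-group's
state (the out-group acts as the ancestral-state proxy) and ambiguous
nodes take their parent's final state (change-delaying, "deltran").
For binary characters the out-group's state always belongs to the root
down-pass set, so the clamped reconstruction attains the Fitch
parsimony score.

A gain on an edge is a 0 -> 1 transition from parent to child; a loss
is 1 -> 0.  The out-group's own pendant edge is never assessed.
Because different most-parsimonious reconstructions can place changes
on different edges, edges are additionally annotated with the number of
characters whose change on that edge is ambiguous (present in some but
not all most-parsimonious reconstructions), computed by exhaustive
enumeration over internal assignments (host trees are small).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import EcocladeError
from .tree import PhyloTree

__all__ = ["GainLossTable", "fitch_states", "gain_loss_counts"]

_MAX_ENUM_INTERNAL = 16


@dataclass
class GainLossTable:
    """Per-edge gain/loss totals plus per-character ancestral states.

    ``edges`` is indexed by the child node id of each edge, with
    columns gains, losses, ambiguous and assessed (False only for the
    out-group's pendant edge).  ``states`` is nodes x characters.
    """

    tree: PhyloTree                     # rooted on the out-group edge
    outgroup: str
    edges: pd.DataFrame
    states: pd.DataFrame

    @property
    def total_gains(self) -> int:
        return int(self.edges.loc[self.edges["assessed"], "gains"].sum())

    @property
    def total_losses(self) -> int:
        return int(self.edges.loc[self.edges["assessed"], "losses"].sum())


def _check_states(tip_states: Mapping[str, int], tips) -> None:
    missing = [t for t in tips if t not in tip_states]
    if missing:
        raise EcocladeError(f"missing tip states for: {', '.join(missing)}")
    bad = {t: v for t, v in tip_states.items() if v not in (0, 1)}
    if bad:
        raise EcocladeError(f"non-binary character states: {bad}")


def _fitch_on_rooted(
    tree: PhyloTree, tip_states: Mapping[str, int], root_state: int
) -> Tuple[Dict[str, int], int]:
    """Down-pass + change-delaying up-pass with the root clamped.

    Returns (state per node, number of changes).
    """
    down: Dict[str, frozenset] = {}
    order = []

    def post(node_id: str):
        kids = tree.children_ids(node_id)
        if not kids:
            down[node_id] = frozenset({tip_states[node_id]})
        else:
            sets = [post(c) for c in kids]
            inter = frozenset.intersection(*sets)
            down[node_id] = inter if inter else frozenset.union(*sets)
        order.append(node_id)
        return down[node_id]

    post(tree.root_id)
    if root_state not in down[tree.root_id]:  # pragma: no cover
        raise EcocladeError("root clamp outside the Fitch set")
    state: Dict[str, int] = {}

    def pre(node_id: str, parent_state: Optional[int]):
        kids = tree.children_ids(node_id)
        if parent_state is None:
            s = root_state
        elif not kids:
            s = tip_states[node_id]
        else:
            s = parent_state if parent_state in down[node_id] \
                else next(iter(down[node_id]))
        state[node_id] = s
        for c in kids:
            pre(c, s)

    pre(tree.root_id, None)
    changes = 0
    for node_id, s in state.items():
        parent = tree.parent_id(node_id)
        if parent is not None and state[parent] != s:
            changes += 1
    return state, changes


def fitch_states(
    host_tree: PhyloTree,
    tip_states: Mapping[str, int],
    outgroup: str,
) -> Tuple[PhyloTree, Dict[str, int]]:
    """Ancestral 0/1 states for one character, out-group rooted.

    Returns ``(rooted_tree, states)`` — rooting on the out-group edge
    reassigns clade ids, so states are keyed to the returned tree.
    """
    rooted = host_tree.root_with_outgroup(outgroup)
    _check_states(tip_states, rooted.tip_labels)
    states, _ = _fitch_on_rooted(rooted, tip_states, int(tip_states[outgroup]))
    return rooted, states


def _min_score_and_edge_changes(
    tree: PhyloTree, tip_states: Mapping[str, int], root_state: int
):
    """Exhaustive minimum-change enumeration with the root clamped.

    Returns (min score, {edge child id -> 'all'|'some'|'none'}) saying
    whether a change on that edge occurs in all / some / none of the
    most-parsimonious reconstructions.
    """
    internal = [c for c in tree.clade_ids if c != tree.root_id]
    if len(internal) > _MAX_ENUM_INTERNAL:
        raise EcocladeError(
            "host tree too large for exhaustive ambiguity enumeration"
        )
    nodes = list(tree.clade_ids) + list(tree.tip_labels)
    edge_children = [n for n in nodes if tree.parent_id(n) is not None]
    best = None
    tallies: Dict[str, list] = {}
    for combo in itertools.product((0, 1), repeat=len(internal)):
        assign = dict(zip(internal, combo))
        assign[tree.root_id] = root_state
        for t in tree.tip_labels:
            assign[t] = int(tip_states[t])
        changed = [c for c in edge_children
                   if assign[c] != assign[tree.parent_id(c)]]
        score = len(changed)
        if best is None or score < best:
            best = score
            tallies = {c: [] for c in edge_children}
            for c in edge_children:
                tallies[c].append(c in changed)
        elif score == best:
            for c in edge_children:
                tallies[c].append(c in changed)
    status = {}
    for c, hits in tallies.items():
        if all(hits):
            status[c] = "all"
        elif any(hits):
            status[c] = "some"
        else:
            status[c] = "none"
    return best, status


def gain_loss_counts(
    host_tree: PhyloTree,
    characters: pd.DataFrame,
    outgroup: str,
    report_ambiguity: bool = True,
) -> GainLossTable:
    """Per-edge gains and losses over a clade x host-group 0/1 matrix.

    ``characters`` has one row per clade (character) and one column per
    host group (tip of the host tree).
    """
    if characters.shape[0] < 1:
        raise EcocladeError("need at least one character")
    vals = characters.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise EcocladeError("character values must be 0/1")
    rooted = host_tree.root_with_outgroup(outgroup)
    tips = rooted.tip_labels
    missing = [t for t in tips if t not in characters.columns]
    if missing:
        raise EcocladeError(
            f"characters lack columns for host tips: {', '.join(missing)}"
        )

    nodes = list(rooted.clade_ids) + list(rooted.tip_labels)
    edge_children = [n for n in nodes if rooted.parent_id(n) is not None]
    gains = {c: 0 for c in edge_children}
    losses = {c: 0 for c in edge_children}
    ambiguous = {c: 0 for c in edge_children}
    states_cols = {}

    # deduplicate character patterns: host trees are tiny, patterns repeat
    patterns: Dict[Tuple[int, ...], Tuple[Dict[str, int], Dict[str, str]]] = {}
    for clade_id, row in characters.iterrows():
        key = tuple(int(row[t]) for t in tips)
        if key not in patterns:
            tip_states = dict(zip(tips, key))
            state, _ = _fitch_on_rooted(rooted, tip_states,
                                        tip_states[outgroup])
            amb: Dict[str, str] = {}
            if report_ambiguity:
                _, amb = _min_score_and_edge_changes(
                    rooted, tip_states, tip_states[outgroup]
                )
            patterns[key] = (state, amb)
        state, amb = patterns[key]
        states_cols[clade_id] = state
        for child in edge_children:
            ps, cs = state[rooted.parent_id(child)], state[child]
            if ps == 0 and cs == 1:
                gains[child] += 1
            elif ps == 1 and cs == 0:
                losses[child] += 1
            if report_ambiguity and amb.get(child) == "some":
                ambiguous[child] += 1

    edges = pd.DataFrame(
        {
            "gains": [gains[c] for c in edge_children],
            "losses": [losses[c] for c in edge_children],
            "ambiguous": [ambiguous[c] for c in edge_children],
            "assessed": [c != outgroup for c in edge_children],
        },
        index=pd.Index(edge_children, name="edge_child"),
    )
    states = pd.DataFrame(states_cols)
    states.index.name = "node_id"
    return GainLossTable(tree=rooted, outgroup=outgroup, edges=edges,
                         states=states)
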