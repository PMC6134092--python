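"""Synthetic communities with planted, verifiable ground truth.

Stands in for real survey data: generates an OTU phylogeny (Yule
topology, exponential branch lengths), a tip x sample count table whose
null occupancy is independent of the tree (each tip draws an occupancy
probability from a Beta distribution, presence is Bernoulli per sample,
positive counts are 1 + Poisson), a monophyletic rank-prefixed taxonomy
obtained by cutting the tree at depth thresholds, grouped sample
metadata, and — on request — planted signals: clades forced to a target
prevalence within a host group, and clades made exclusive to a group.
Every planted property is recorded in a truth registry and re-verified
from the generated table itself, so downstream tests can score recovery
against known ground truth.

Tree-independent occupancy is exactly the exchangeability assumption of
the conservation permutation test, making unplanted scenarios valid
null calibration data.
"""

from __future__ import annotations

import json
import math
import random as _pyrandom
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .community import write_table, write_taxonomy
from .errors import EcocladeError
from .profile import compute_clade_profile
from .tree import PhyloTree

__all__ = [
    "simulate_tree", "simulate_null_table", "plant_conserved_clade",
    "simulate_taxonomy", "simulate_dataset", "ScenarioConfig", "PlantSpec",
    "SyntheticDataset", "SCENARIOS",
]

_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
DEFAULT_RANK_DEPTHS = {
    "k__": 0.10, "p__": 0.25, "c__": 0.40, "o__": 0.55,
    "f__": 0.70, "g__": 0.82, "s__": 0.92,
}


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_tree(n_tips: int, seed=None) -> PhyloTree:
    """Yule (pure-birth) topology with exponential(1) branch lengths.

    Tips are named ``OTU_0001`` ... in the order the simulator emits
    them; the returned tree carries canonical clade ids.
    """
    if n_tips < 2:
        raise EcocladeError("need at least 2 tips")
    from dendropy.simulate import treesim

    rng = _as_rng(seed)
    py_rng = _pyrandom.Random(int(rng.integers(2**31)))
    dtree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips, rng=py_rng,
    )
    for i, leaf in enumerate(dtree.leaf_node_iter()):
        leaf.taxon.label = f"OTU_{i + 1:04d}"
    for edge in dtree.preorder_edge_iter():
        if edge.head_node is not dtree.seed_node:
            edge.length = float(rng.exponential(1.0))
    newick = dtree.as_string(schema="newick", suppress_rooting=True)
    return PhyloTree.from_newick(newick)


def simulate_null_table(
    tree: PhyloTree,
    n_samples: int,
    prevalence_alpha: float = 1.0,
    prevalence_beta: float = 4.0,
    abundance_mean: float = 10.0,
    seed=None,
    sample_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Tree-independent null community table.

    Each tip t draws an occupancy probability pi_t ~ Beta(alpha, beta);
    presence is Bernoulli(pi_t) per sample; positive counts are
    1 + Poisson(abundance_mean).
    """
    if n_samples < 1:
        raise EcocladeError("need at least 1 sample")
    if prevalence_alpha <= 0 or prevalence_beta <= 0 or abundance_mean < 0:
        raise EcocladeError("invalid occupancy/abundance hyperparameters")
    rng = _as_rng(seed)
    tips = tree.tip_labels
    if sample_ids is None:
        sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    elif len(sample_ids) != n_samples:
        raise EcocladeError("sample_ids length does not match n_samples")
    pi = rng.beta(prevalence_alpha, prevalence_beta, size=len(tips))
    present = rng.random((len(tips), n_samples)) < pi[:, None]
    counts = np.where(present, 1 + rng.poisson(abundance_mean,
                                               (len(tips), n_samples)), 0)
    return pd.DataFrame(counts, index=pd.Index(tips, name="otu_id"),
                        columns=list(sample_ids))


def plant_conserved_clade(
    table: pd.DataFrame,
    tree: PhyloTree,
    clade: str,
    samples: Sequence[str],
    target_prevalence: float = 1.0,
    rng=None,
    abundance_mean: float = 10.0,
) -> Tuple[pd.DataFrame, Dict]:
    """Force a clade to (at least) a target prevalence over target samples.

    In enough target samples currently lacking the clade, one uniformly
    chosen member tip's count is set to a positive value.  Counts of
    non-member tips are never touched; a clade already at the target is
    left unchanged.
    """
    if not (0 < target_prevalence <= 1):
        raise EcocladeError("target_prevalence must be in (0, 1]")
    rng = _as_rng(rng)
    members = list(tree.clade_tips(clade))
    samples = list(samples)
    need = math.ceil(target_prevalence * len(samples))
    out = table.copy()
    present = (out.loc[members, samples] > 0).any(axis=0)
    lacking = [s for s in samples if not present[s]]
    n_fix = max(0, need - (len(samples) - len(lacking)))
    chosen = list(rng.choice(len(lacking), size=n_fix, replace=False)) \
        if n_fix else []
    for i in chosen:
        tip = members[int(rng.integers(len(members)))]
        out.loc[tip, lacking[i]] = 1 + int(rng.poisson(abundance_mean))
    realized = int((out.loc[members, samples] > 0).any(axis=0).sum())
    truth = {
        "clade_id": clade,
        "n_tips": len(members),
        "samples": samples,
        "target_prevalence": target_prevalence,
        "realized_prevalence": realized,
    }
    return out, truth


def simulate_taxonomy(
    tree: PhyloTree,
    rank_depths: Optional[Mapping[str, float]] = None,
    seed=None,
) -> Dict[str, str]:
    """Monophyletic taxonomy from depth cuts of the tree.

    For each rank, the tree is cut at ``quantile x (max tip depth)``
    from the root: every tip is labelled by the highest node at or
    below the cut on its root-to-tip path, so each rank label is
    monophyletic by construction and ranks nest (quantiles ascend).
    Tips whose path never reaches a cut (shallow tips) become their own
    singleton taxon at that rank.
    """
    rank_depths = dict(rank_depths or DEFAULT_RANK_DEPTHS)
    depths = tree.depths()
    max_depth = max(depths[t] for t in tree.tip_labels)
    if max_depth <= 0:
        raise EcocladeError("tree has no depth variation")

    lineages: Dict[str, List[str]] = {t: [] for t in tree.tip_labels}
    for prefix in _RANK_PREFIXES:
        if prefix not in rank_depths:
            continue
        cut = rank_depths[prefix] * max_depth
        counter = 0

        def walk(node_id: str) -> None:
            nonlocal counter
            if depths[node_id] >= cut or not tree.children_ids(node_id):
                counter += 1
                label = f"{prefix}{prefix[0].upper()}{counter}"
                for t in tree.clade_tips(node_id):
                    lineages[t].append(label)
                return
            for c in tree.children_ids(node_id):
                walk(c)

        walk(tree.root_id)
    return {t: ";".join(parts) for t, parts in lineages.items()}


@dataclass
class PlantSpec:
    """One planted conservation signal."""

    clade_size: int = 8
    group: str = ""
    prevalence: float = 1.0
    exclusive: bool = False


@dataclass
class ScenarioConfig:
    """Full specification of a synthetic study."""

    n_tips: int = 64
    groups: Dict[str, int] = field(default_factory=lambda: {"GroupA": 24})
    group_column: str = "host_order"
    prevalence_alpha: float = 1.0
    prevalence_beta: float = 4.0
    abundance_mean: float = 10.0
    planted: List[PlantSpec] = field(default_factory=list)
    host_tree_newick: Optional[str] = None

    def validate(self) -> None:
        if self.n_tips < 2:
            raise EcocladeError("config field n_tips: need >= 2")
        if not self.groups:
            raise EcocladeError("config field groups: need >= 1 group")
        for g, n in self.groups.items():
            if n < 1:
                raise EcocladeError(f"config field groups[{g}]: need >= 1 sample")
        for spec in self.planted:
            if spec.group and spec.group not in self.groups:
                raise EcocladeError(
                    f"config field planted.group: unknown group {spec.group!r}"
                )
            if not (0 < spec.prevalence <= 1):
                raise EcocladeError(
                    "config field planted.prevalence: must be in (0, 1]"
                )
            if spec.clade_size < 2 or spec.clade_size > self.n_tips:
                raise EcocladeError(
                    "config field planted.clade_size: out of range"
                )

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        d = dict(d)
        planted = [PlantSpec(**p) for p in d.pop("planted", [])]
        return cls(planted=planted, **d)


@dataclass
class SyntheticDataset:
    tree: PhyloTree
    table: pd.DataFrame
    taxonomy: Dict[str, str]
    metadata: pd.DataFrame
    truth: Dict
    config: ScenarioConfig

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.tree.write(out / "tree.nwk")
        write_table(self.table, out / "table.tsv")
        write_taxonomy(self.taxonomy, out / "taxonomy.tsv")
        self.metadata.to_csv(out / "metadata.tsv", sep="\t")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
        if self.config.host_tree_newick:
            with open(out / "host_tree.nwk", "w") as fh:
                fh.write(self.config.host_tree_newick.strip() + "\n")


def _pick_clade(tree: PhyloTree, size: int, rng, exclude=()) -> str:
    """Deterministically pick an internal clade of (closest to) a size."""
    sizes = {c: len(tree.clade_tips(c)) for c in tree.clade_ids
             if c != tree.root_id and c not in exclude}
    if not sizes:
        raise EcocladeError("no internal clades available for planting")
    best_diff = min(abs(v - size) for v in sizes.values())
    candidates = sorted(c for c, v in sizes.items()
                        if abs(v - size) == best_diff)
    return candidates[int(rng.integers(len(candidates)))]


_DIETS = ("omnivore", "herbivore", "carnivore")


def simulate_dataset(
    config: Union[ScenarioConfig, str, Mapping],
    seed=None,
) -> SyntheticDataset:
    """Compose tree, table, taxonomy, metadata and planted signals.

    ``config`` may be a :class:`ScenarioConfig`, the name of a built-in
    scenario (see ``SCENARIOS``), or a plain mapping.  Generation is a
    pure function of (config, seed).
    """
    if isinstance(config, str):
        try:
            config = SCENARIOS[config]()
        except KeyError:
            raise EcocladeError(
                f"unknown scenario {config!r}; available: "
                + ", ".join(sorted(SCENARIOS))
            ) from None
    elif isinstance(config, Mapping):
        config = ScenarioConfig.from_dict(config)
    config.validate()
    rng = _as_rng(seed)

    tree = simulate_tree(config.n_tips, rng)
    sample_ids, rows = [], []
    for gi, (group, n) in enumerate(config.groups.items()):
        for i in range(n):
            sid = f"{group}_{i + 1:03d}"
            sample_ids.append(sid)
            rows.append({
                "sample_id": sid,
                config.group_column: group,
                "host_species": group,
                "diet": _DIETS[gi % len(_DIETS)],
            })
    metadata = pd.DataFrame(rows).set_index("sample_id")
    table = simulate_null_table(
        tree, len(sample_ids),
        prevalence_alpha=config.prevalence_alpha,
        prevalence_beta=config.prevalence_beta,
        abundance_mean=config.abundance_mean,
        seed=rng, sample_ids=sample_ids,
    )

    truth: Dict = {"planted": [], "exclusive": [], "groups": dict(config.groups)}
    used: List[str] = []
    for spec in config.planted:
        group = spec.group or next(iter(config.groups))
        targets = [s for s in sample_ids
                   if metadata.loc[s, config.group_column] == group]
        clade = _pick_clade(tree, spec.clade_size, rng, exclude=used)
        used.append(clade)
        if spec.exclusive:
            members = list(tree.clade_tips(clade))
            outside = [s for s in sample_ids if s not in targets]
            table.loc[members, outside] = 0
        table, record = plant_conserved_clade(
            table, tree, clade, targets, spec.prevalence, rng,
            abundance_mean=config.abundance_mean,
        )
        record["group"] = group
        record["samples"] = targets
        truth["planted"].append(record)
        if spec.exclusive:
            truth["exclusive"].append(clade)

    # verify the registry against the emitted table
    profile = compute_clade_profile(tree, table)
    for record in truth["planted"]:
        prev = int(profile.presence.loc[record["clade_id"],
                                        record["samples"]].sum())
        if prev < math.ceil(record["target_prevalence"]
                            * len(record["samples"])):
            raise EcocladeError("planted prevalence not realized")  # pragma: no cover
        record["realized_prevalence"] = prev
    return SyntheticDataset(tree=tree, table=table,
                            taxonomy=simulate_taxonomy(tree),
                            metadata=metadata, truth=truth, config=config)


def _null_scenario() -> ScenarioConfig:
    return ScenarioConfig(n_tips=64, groups={"GroupA": 24})


def _two_orders_one_planted() -> ScenarioConfig:
    # detection scenarios use Beta(4,16) occupancy: same 0.2 mean tip
    # prevalence as the null default, but moderate dispersion, under
    # which the permutation z test has power (see docs/methods.md)
    return ScenarioConfig(
        n_tips=64,
        groups={"Primates": 20, "Carnivora": 20},
        prevalence_alpha=4.0, prevalence_beta=16.0,
        planted=[PlantSpec(clade_size=2, group="Primates", prevalence=1.0)],
    )


def _three_orders_structure() -> ScenarioConfig:
    return ScenarioConfig(
        n_tips=96,
        groups={"Primates": 16, "Carnivora": 16, "Artiodactyla": 16},
        prevalence_alpha=4.0, prevalence_beta=16.0,
        planted=[
            PlantSpec(clade_size=3, group="Primates", prevalence=1.0),
            PlantSpec(clade_size=3, group="Carnivora", prevalence=1.0,
                      exclusive=True),
        ],
    )


def _hominids() -> ScenarioConfig:
    return ScenarioConfig(
        n_tips=64,
        groups={"chimp": 8, "bonobo": 8, "gorilla": 8,
                "human_western": 8, "human_nonwestern": 8},
        group_column="host_species",
        prevalence_alpha=4.0, prevalence_beta=16.0,
        planted=[PlantSpec(clade_size=2, group="chimp", prevalence=1.0)],
        host_tree_newick=(
            "(((chimp:1,bonobo:1):2,(human_western:1,"
            "human_nonwestern:1):2):3,gorilla:6);"
        ),
    )


SCENARIOS = {
    "null": _null_scenario,
    "two_orders_one_planted": _two_orders_one_planted,
    "three_orders_structure": _three_orders_structure,
    "hominids": _hominids,
}
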