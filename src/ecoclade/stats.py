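"""Ecophylogenetic statistics.

Beta-diversity (Bray-Curtis, abundance-weighted or presence-absence),
Shannon entropy, single-factor PERMANOVA (Anderson's distance-based
formulation with label-permutation p-values), the Mantel test, the
sample-level host phylogenetic distance matrix, and the phylogenetic
clustering test of conserved clades (two-sample Kolmogorov–Smirnov
against pairwise distances of uniformly resampled internal nodes).

Distance matrices are ``skbio.DistanceMatrix`` objects.  Permutation
p-values follow the add-one convention p = (1 + #{stat_perm >= stat}) /
(n_perm + 1), so the smallest attainable p is 1/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import entropy as _scipy_entropy
from scipy.stats import ks_2samp
from skbio import DistanceMatrix

from .errors import EcocladeError
from .tree import PhyloTree

__all__ = [
    "StatResult", "bray_curtis", "shannon_entropy", "permanova", "mantel",
    "host_distance_matrix", "clade_clustering_test",
]


@dataclass
class StatResult:
    """A permutation-test result: named statistic, value, p, provenance."""

    statistic: str
    value: float
    p_value: float
    n_perm: Optional[int] = None
    seed: Optional[int] = None
    extra: Dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        row = {"statistic": self.statistic, "value": self.value,
               "p_value": self.p_value, "n_perm": self.n_perm,
               "seed": self.seed, **self.extra}
        return pd.DataFrame([row])


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def bray_curtis(
    matrix: pd.DataFrame, weighted: bool = True
) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples (columns).

    ``weighted=False`` binarises the matrix first, giving the
    presence-absence variant (Sørensen dissimilarity).
    """
    if matrix.shape[1] < 2:
        raise EcocladeError("need at least 2 samples")
    zero = matrix.columns[(matrix.sum(axis=0) == 0)]
    if len(zero):
        raise EcocladeError(
            f"all-zero sample(s): {', '.join(map(str, zero))}"
        )
    X = matrix.to_numpy(dtype=float).T
    if not weighted:
        X = (X > 0).astype(float)
    cond = pdist(X, metric="braycurtis")
    return DistanceMatrix(squareform(cond), ids=[str(c) for c in matrix.columns])


def shannon_entropy(counts: Iterable[float]) -> float:
    """Shannon entropy (nats) of a count vector."""
    c = np.asarray(list(counts), dtype=float)
    if c.sum() <= 0:
        raise EcocladeError("cannot compute entropy of an all-zero vector")
    return float(_scipy_entropy(c))


def _permanova_ss(d2: np.ndarray, labels: np.ndarray):
    """Within-group and total sums of squared distances (Anderson)."""
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    sst = d2[iu].sum() / n
    ssw = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ssw, sst


def permanova(
    dm: DistanceMatrix,
    labels: Union[pd.Series, Sequence],
    n_perm: int = 1000,
    seed: Union[None, int, np.random.Generator] = None,
) -> StatResult:
    """Single-factor PERMANOVA: pseudo-F, R², permutation p-value."""
    if isinstance(labels, pd.Series):
        labels = labels.loc[list(dm.ids)]
    labels = np.asarray(labels)
    if len(labels) != dm.shape[0]:
        raise EcocladeError("labels do not match distance matrix size")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise EcocladeError("PERMANOVA needs at least 2 groups")
    n, a = len(labels), len(uniq)
    d2 = dm.data ** 2

    def pseudo_f(lab):
        ssw, sst = _permanova_ss(d2, lab)
        ssa = sst - ssw
        if ssw <= 0:
            return np.inf, ssa / sst if sst > 0 else np.nan
        return (ssa / (a - 1)) / (ssw / (n - a)), ssa / sst

    f_obs, r2 = pseudo_f(labels)
    rng = _as_rng(seed)
    count = 0
    for _ in range(n_perm):
        f_perm, _ = pseudo_f(labels[rng.permutation(n)])
        if f_perm >= f_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return StatResult("pseudo_F", float(f_obs), p, n_perm=n_perm,
                      seed=_maybe_int(seed), extra={"r2": float(r2)})


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 1000,
    seed: Union[None, int, np.random.Generator] = None,
    alternative: str = "greater",
) -> StatResult:
    """Mantel test: Pearson correlation of two distance matrices.

    p by simultaneous row/column permutation of the second matrix;
    ``alternative`` is ``"greater"`` (the convention of vegan's mantel)
    or ``"two-sided"``.
    """
    if d1.shape[0] != d2.shape[0]:
        raise EcocladeError("distance matrices differ in size")
    if d1.shape[0] < 3:
        raise EcocladeError("Mantel test needs at least 3 objects")
    if set(d1.ids) != set(d2.ids):
        raise EcocladeError("distance matrices have different ids")
    d2 = d2.filter(d1.ids)
    iu = np.triu_indices(d1.shape[0], 1)
    x = d1.data[iu]
    y0 = d2.data

    def corr(mat):
        return np.corrcoef(x, mat[iu])[0, 1]

    r_obs = corr(y0)
    rng = _as_rng(seed)
    count = 0
    n = d1.shape[0]
    for _ in range(n_perm):
        idx = rng.permutation(n)
        r_perm = corr(y0[np.ix_(idx, idx)])
        if alternative == "two-sided":
            hit = abs(r_perm) >= abs(r_obs) - 1e-12
        else:
            hit = r_perm >= r_obs - 1e-12
        count += hit
    p = (1 + count) / (n_perm + 1)
    return StatResult("mantel_r", float(r_obs), p, n_perm=n_perm,
                      seed=_maybe_int(seed))


def host_distance_matrix(
    host_tree: PhyloTree,
    metadata: pd.DataFrame,
    species_column: str,
) -> DistanceMatrix:
    """Sample x sample patristic distances between host species.

    Conspecific samples are at distance 0.  Every sample's species must
    be a tip of the host tree.
    """
    if species_column not in metadata.columns:
        raise EcocladeError(f"unknown metadata column {species_column!r}")
    species = metadata[species_column]
    tips = set(host_tree.tip_labels)
    unmapped = sorted(set(species) - tips)
    if unmapped:
        raise EcocladeError(
            "species not in host tree: " + ", ".join(map(str, unmapped))
        )
    uniq = sorted(set(species))
    base = host_tree.patristic_matrix(uniq)
    samples = list(metadata.index)
    idx = [uniq.index(species.loc[s]) for s in samples]
    mat = base.to_numpy()[np.ix_(idx, idx)]
    return DistanceMatrix(mat, ids=[str(s) for s in samples])


def clade_clustering_test(
    tree: PhyloTree,
    conserved: Iterable[str],
    n_boot: int = 1000,
    exclude_nested: bool = False,
    seed: Union[None, int, np.random.Generator] = None,
) -> StatResult:
    """Are conserved clades phylogenetically clustered?

    Compares the pairwise patristic distances between conserved clade
    nodes against a pooled null of distances between equally many
    internal nodes drawn uniformly without replacement (``n_boot``
    draws), via a two-sample two-sided KS test.  The direction
    ("clustered" when the observed mean distance is below the null
    mean) is reported alongside.

    ``exclude_nested`` drops conserved clades whose parent is also
    conserved before testing (robustness to signal propagation along
    the tree).
    """
    conserved = set(conserved)
    unknown = [c for c in conserved if c not in set(tree.clade_ids)]
    if unknown:
        raise EcocladeError(f"not internal clades: {', '.join(sorted(unknown))}")
    if exclude_nested:
        conserved = {
            c for c in conserved if tree.parent_id(c) not in conserved
        }
    conserved = sorted(conserved)
    k = len(conserved)
    if k < 2:
        raise EcocladeError("need >= 2 conserved clades to test clustering")
    pool_ids = tree.clade_ids
    if k > len(pool_ids):
        raise EcocladeError("more conserved clades than internal nodes")
    full = tree.patristic_matrix(pool_ids).to_numpy()
    index = {c: i for i, c in enumerate(pool_ids)}
    iu_k = np.triu_indices(k, 1)
    obs_idx = np.array([index[c] for c in conserved])
    observed = full[np.ix_(obs_idx, obs_idx)][iu_k]

    rng = _as_rng(seed)
    null_parts = []
    m = len(pool_ids)
    for _ in range(n_boot):
        pick = rng.choice(m, size=k, replace=False)
        null_parts.append(full[np.ix_(pick, pick)][iu_k])
    null = np.concatenate(null_parts)
    stat = ks_2samp(observed, null)
    direction = "clustered" if observed.mean() < null.mean() else "dispersed"
    return StatResult(
        "ks_D", float(stat.statistic), float(stat.pvalue), n_perm=n_boot,
        seed=_maybe_int(seed),
        extra={"n_clades": float(k),
               "mean_observed": float(observed.mean()),
               "mean_null": float(null.mean()),
               "direction": direction},
    )


def _maybe_int(seed) -> Optional[int]:
    return seed if isinstance(seed, (int, np.integer)) else None
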