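"""The phylogenetic permutation test for clade conservation.

A clade is *conserved* across a set of communities when its prevalence
(number of communities where any member tip is detected) exceeds what
is expected given the prevalences of the tips themselves.  The null
model shuffles tip-to-community presence rows across the tips of the
phylogeny: each tip keeps some row of the observed presence matrix, so
the per-tip prevalence distribution and the per-sample richness are
exactly preserved, while the association between presence patterns and
tree position is destroyed.  Repeating the shuffle ``n_perm`` times
(1,000 by default; 100 is a documented fallback for very large trees)
yields a null prevalence distribution per clade, summarised by its mean
and population standard deviation; a one-sided z test asks whether the
observed prevalence is greater than that null, and Benjamini–Hochberg
FDR correction across all clades of one invocation produces q-values.

Clades whose null is degenerate (sd == 0, notably the all-tips root
clade, whose prevalence is permutation-invariant) are never significant
unless observed > null mean, which is impossible for the root; they are
flagged ``degenerate_null`` in the output.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .errors import EcocladeError
from .profile import CladeProfile, compute_clade_profile, label_clade_taxonomy
from .tree import PhyloTree

__all__ = [
    "permute_presence",
    "null_prevalence",
    "z_test_prevalence",
    "bh_fdr",
    "test_conservation",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = [
    "clade_id", "group", "n_tips", "taxonomy_label", "n_group_samples",
    "observed_prevalence", "prevalence_fraction", "null_mean", "null_sd",
    "z_score", "p_value", "q_value", "conserved", "exclusive",
    "uniquely_conserved", "degenerate_null",
]


def _as_rng(seed: Union[None, int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def permute_presence(
    presence: Union[np.ndarray, pd.DataFrame],
    rng: Union[None, int, np.random.Generator] = None,
) -> Union[np.ndarray, pd.DataFrame]:
    """Shuffle tip-to-community presence rows by a uniform permutation.

    The multiset of row vectors — hence every per-sample column sum and
    the overall prevalence distribution — is exactly preserved.
    """
    rng = _as_rng(rng)
    if isinstance(presence, pd.DataFrame):
        values = presence.to_numpy()
        idx = rng.permutation(values.shape[0])
        return pd.DataFrame(values[idx], index=presence.index,
                            columns=presence.columns)
    presence = np.asarray(presence)
    if presence.size == 0:
        raise EcocladeError("empty presence matrix")
    return presence[rng.permutation(presence.shape[0])]


def null_prevalence(
    tree: PhyloTree,
    tip_presence: pd.DataFrame,
    samples: Optional[Sequence[str]] = None,
    n_perm: int = 1000,
    rng: Union[None, int, np.random.Generator] = None,
    return_draws: bool = False,
) -> pd.DataFrame:
    """Permutation-null mean and sd of each clade's prevalence.

    One shared permutation stream evaluates all clades simultaneously
    per permutation.  The sd is the population sd (ddof=0) of the
    ``n_perm`` draws.  With ``return_draws`` the full clade x n_perm
    draw matrix is attached as ``.attrs["draws"]``.
    """
    if n_perm < 1:
        raise EcocladeError("n_perm must be >= 1")
    rng = _as_rng(rng)
    cols = list(samples) if samples is not None else list(tip_presence.columns)
    if not cols:
        raise EcocladeError("empty sample subset")
    P = tip_presence.loc[tree.tip_labels, cols].to_numpy(dtype=np.float32)
    n_tips = P.shape[0]
    clade_ids = tree.clade_ids
    M = np.zeros((len(clade_ids), n_tips), dtype=np.float32)
    tip_idx = {t: i for i, t in enumerate(tree.tip_labels)}
    for ci, cid in enumerate(clade_ids):
        for t in tree.clade_tips(cid):
            M[ci, tip_idx[t]] = 1.0

    draws = np.empty((len(clade_ids), n_perm), dtype=np.int32)
    for k in range(n_perm):
        idx = rng.permutation(n_tips)
        member_hits = M @ P[idx]
        draws[:, k] = (member_hits > 0).sum(axis=1)
    mean = draws.mean(axis=1)
    sd = draws.std(axis=1, ddof=0)
    out = pd.DataFrame(
        {"null_mean": mean, "null_sd": sd},
        index=pd.Index(clade_ids, name="clade_id"),
    )
    if return_draws:
        out.attrs["draws"] = draws
    return out


def z_test_prevalence(
    observed: Union[float, np.ndarray],
    null_mean: Union[float, np.ndarray],
    null_sd: Union[float, np.ndarray],
) -> Tuple[np.ndarray, np.ndarray]:
    """One-sided ("greater") z test of observed prevalence against the null.

    With a degenerate null (sd == 0): p = 1 if observed <= mean, else 0.
    Scalars in, scalars out.
    """
    obs = np.asarray(observed, dtype=float)
    mu = np.asarray(null_mean, dtype=float)
    sd = np.asarray(null_sd, dtype=float)
    if np.any(sd < 0):
        raise EcocladeError("null_sd must be nonnegative")
    scalar = obs.ndim == 0
    obs, mu, sd = np.atleast_1d(obs), np.atleast_1d(mu), np.atleast_1d(sd)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (obs - mu) / np.where(sd > 0, sd, 1.0),
                     np.where(obs > mu, np.inf, np.where(obs < mu, -np.inf, 0.0)))
    p = norm.sf(z)
    degenerate = sd == 0
    p = np.where(degenerate, np.where(obs > mu, 0.0, 1.0), p)
    if scalar:
        return float(z[0]), float(p[0])
    return z, p


def bh_fdr(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise EcocladeError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_conservation(
    tree: PhyloTree,
    table: pd.DataFrame,
    metadata: Optional[pd.DataFrame] = None,
    group_column: Optional[str] = None,
    group_value: str = "ALL",
    *,
    taxonomy: Optional[Mapping[str, str]] = None,
    n_perm: int = 1000,
    seed: Union[None, int, np.random.Generator] = None,
    presence_threshold: float = 1.0,
    alpha: float = 0.2,
    empirical_p: bool = False,
    profile: Optional[CladeProfile] = None,
) -> pd.DataFrame:
    """Scan every clade of the tree for conservation across a sample group.

    Parameters
    ----------
    group_value
        A value of ``metadata[group_column]`` selecting the samples to
        test, or ``"ALL"`` for every sample of the table.
    n_perm, seed
        Permutation count and RNG seed; identical inputs and seed give
        bit-identical results.
    alpha
        FDR threshold for the ``conserved`` call (q < alpha).
    empirical_p
        Replace the parametric z-test p-value with the empirical one,
        p = (1 + #{null >= obs}) / (n_perm + 1).

    Returns a DataFrame with one row per clade (see ``RESULT_COLUMNS``).
    """
    if profile is None:
        profile = compute_clade_profile(tree, table,
                                        presence_threshold=presence_threshold)
    all_samples = profile.sample_ids
    if group_value == "ALL":
        group_samples = list(all_samples)
    else:
        if metadata is None or group_column is None:
            raise EcocladeError(
                "metadata and group_column are required for group tests"
            )
        if group_column not in metadata.columns:
            raise EcocladeError(
                f"unknown group column {group_column!r}; available: "
                + ", ".join(metadata.columns)
            )
        col = metadata[group_column]
        group_samples = [
            s for s in all_samples
            if s in metadata.index and col.loc[s] == group_value
        ]
        if not group_samples:
            available = sorted(col.dropna().unique())
            raise EcocladeError(
                f"no samples with {group_column}={group_value!r}; "
                f"available values: {', '.join(map(str, available))}"
            )
    if len(group_samples) < 2:
        raise EcocladeError("group must contain at least 2 samples")

    rng = _as_rng(seed)
    null = null_prevalence(
        tree, profile.tip_presence, group_samples, n_perm=n_perm, rng=rng,
        return_draws=empirical_p,
    )
    clade_ids = profile.clade_ids
    obs = profile.presence[group_samples].sum(axis=1).to_numpy(dtype=float)
    mu = null["null_mean"].to_numpy()
    sd = null["null_sd"].to_numpy()
    z, p = z_test_prevalence(obs, mu, sd)
    degenerate = sd == 0
    if empirical_p:
        draws = null.attrs["draws"]
        p = (1.0 + (draws >= obs[:, None]).sum(axis=1)) / (n_perm + 1.0)
    q = bh_fdr(p)
    conserved = (q < alpha) & (obs > mu)

    n_group = len(group_samples)
    complement = [s for s in all_samples if s not in set(group_samples)]
    if complement:
        in_group = profile.presence[group_samples].sum(axis=1) > 0
        outside = profile.presence[complement].sum(axis=1) > 0
        exclusive = (in_group & ~outside).to_numpy()
    else:
        exclusive = np.zeros(len(clade_ids), dtype=bool)

    n_tips = [len(profile.membership(c)) for c in clade_ids]
    labels = [
        label_clade_taxonomy(profile, c, taxonomy) if taxonomy is not None
        else "Unclassified"
        for c in clade_ids
    ]
    out = pd.DataFrame(
        {
            "clade_id": clade_ids,
            "group": group_value,
            "n_tips": n_tips,
            "taxonomy_label": labels,
            "n_group_samples": n_group,
            "observed_prevalence": obs.astype(int),
            "prevalence_fraction": obs / n_group,
            "null_mean": mu,
            "null_sd": sd,
            "z_score": z,
            "p_value": p,
            "q_value": q,
            "conserved": conserved,
            "exclusive": exclusive,
            "uniquely_conserved": False,
            "degenerate_null": degenerate,
        },
        columns=RESULT_COLUMNS,
    )
    return out
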