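"""Dufrene-Legendre indicator species analysis (IndVal).

For a species s and a site group g the indicator value combines

* specificity A_sg: the group's mean abundance of s divided by the sum of
  that mean over all groups (group means, not totals, so unequal group
  sizes do not bias A), and
* fidelity B_sg: the fraction of group-g sites where s occurs.

IndVal_sg = 100 * A_sg * B_sg; the species' indicator value is the maximum
over groups, reaching 100 only for a species found in every site of exactly
one group and nowhere else. Significance of the max statistic is assessed
by shuffling site-group labels; one test per species, Bonferroni-adjusted
across species.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import CommunityTable, ValidationError

__all__ = ["indval_components", "indval_observed", "indval_test"]


def _group_matrices(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-hot (sites x groups) membership and per-group site counts."""
    groups, inv = np.unique(labels, return_inverse=True)
    member = np.zeros((len(labels), len(groups)))
    member[np.arange(len(labels)), inv] = 1.0
    sizes = member.sum(axis=0)
    if np.any(sizes == 0):
        raise ValidationError("every group needs at least one site")
    return member, sizes


def _indval_matrix(X: np.ndarray, member: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """IndVal percentage per (group, species); NaN-free, 0 for absent species."""
    group_mean = (member.T @ X) / sizes[:, None]          # groups x species
    denom = group_mean.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(denom > 0, group_mean / np.where(denom > 0, denom, 1.0), 0.0)
    B = (member.T @ (X > 0)) / sizes[:, None]
    return 100.0 * A * B


def indval_components(
    community: CommunityTable, labels, value_field: str = "ad"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Specificity A and fidelity B per species x group.

    Returns two DataFrames (species rows, group columns). For any species
    present somewhere, A sums to 1 over groups.
    """
    labels = np.asarray(labels)
    X = getattr(community, value_field).to_numpy(dtype=float)
    if np.any(X < 0):
        raise ValidationError("abundances must be non-negative")
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValidationError("need at least two groups")
    member, sizes = _group_matrices(labels)
    group_mean = (member.T @ X) / sizes[:, None]
    denom = group_mean.sum(axis=0)
    A = np.where(denom > 0, group_mean / np.where(denom > 0, denom, 1.0), 0.0)
    B = (member.T @ (X > 0)) / sizes[:, None]
    species = community.species_names
    return (
        pd.DataFrame(A.T, index=species, columns=groups),
        pd.DataFrame(B.T, index=species, columns=groups),
    )


def indval_observed(
    community: CommunityTable, labels, value_field: str = "ad"
) -> pd.DataFrame:
    """Observed per-species IndVal (max over groups) without the test."""
    A, B = indval_components(community, labels, value_field)
    iv = 100.0 * A * B
    best = iv.idxmax(axis=1)
    rows = {
        "best_group": best,
        "A": A.to_numpy()[np.arange(len(A)), A.columns.get_indexer(best)],
        "Bf": B.to_numpy()[np.arange(len(B)), B.columns.get_indexer(best)],
        "indval": iv.max(axis=1),
    }
    return pd.DataFrame(rows, index=iv.index)


def indval_test(
    community: CommunityTable,
    labels,
    n_perm: int = 9999,
    seed: int | None = None,
    adjustment: str = "bonferroni",
    value_field: str = "ad",
) -> pd.DataFrame:
    """IndVal with a permutation test of each species' max-over-groups value.

    The null shuffles site labels ``n_perm`` times, recomputing every
    species' max IndVal per shuffle; p_raw = (1 + #{null >= observed}) /
    (1 + n_perm), so p_raw >= 1/(n_perm+1). Bonferroni multiplies by the
    number of species tested (one max-statistic test per species), capped
    at 1.

    Returns a DataFrame indexed by species with columns best_group, A, Bf,
    indval, p_raw, p_adjusted.
    """
    if adjustment not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    out = indval_observed(community, labels, value_field)
    X = getattr(community, value_field).to_numpy(dtype=float)
    member, sizes = _group_matrices(labels)
    observed = out["indval"].to_numpy()

    rng = np.random.default_rng(seed)
    hits = np.zeros(len(observed))
    for _ in range(n_perm):
        perm = rng.permutation(len(labels))
        null = _indval_matrix(X[perm], member, sizes).max(axis=0)
        hits += null >= observed
    p_raw = (1 + hits) / (1 + n_perm)
    out["p_raw"] = p_raw
    n_tests = len(out)
    if adjustment == "bonferroni":
        out["p_adjusted"] = np.minimum(1.0, p_raw * n_tests)
    else:
        out["p_adjusted"] = p_raw
    return out
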