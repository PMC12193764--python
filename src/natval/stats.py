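"""Community distance and inferential statistics.

Bray-Curtis dissimilarities between trap catches, one-way and pairwise
ANOSIM with permutation p-values, Kendall's tau-b and the Shapiro-Wilk
normality check used on the INV distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kendalltau, rankdata, shapiro

from .core import CommunityTable, UNCLASSIFIED, ValidationError

__all__ = [
    "DistanceMatrix",
    "AnosimResult",
    "CorrelationResult",
    "NormalityResult",
    "bray_curtis_matrix",
    "anosim",
    "pairwise_anosim",
    "kendall_tau_b",
    "shapiro_wilk",
]

logger = logging.getLogger("natval")


@dataclass
class DistanceMatrix:
    """Symmetric site dissimilarity matrix with stable labels."""

    labels: list[str]
    values: np.ndarray  # square form

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        self.values = v

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def subset(self, keep: np.ndarray) -> "DistanceMatrix":
        idx = np.flatnonzero(keep) if keep.dtype == bool else np.asarray(keep)
        return DistanceMatrix(
            labels=[self.labels[i] for i in idx],
            values=self.values[np.ix_(idx, idx)],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class AnosimResult:
    R: float
    p: float
    n_permutations: int
    groups: list[str]
    n_sites: int


@dataclass
class CorrelationResult:
    tau_b: float
    p: float
    n: int


@dataclass
class NormalityResult:
    W: float
    p: float


def bray_curtis_matrix(
    community: CommunityTable, value_field: str = "ad"
) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between traps.

    d(i,j) = sum_s |x_is - x_js| / sum_s (x_is + x_js); 0 for identical
    catches, 1 for fully disjoint species sets. ``value_field`` selects the
    abundance currency: ``"ad"`` (activity density, the default for pitfall
    data) or ``"counts"``.
    """
    if value_field not in ("ad", "counts"):
        raise ValueError(f"value_field must be 'ad' or 'counts', got {value_field!r}")
    X = getattr(community, value_field).to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValidationError("need at least two traps for a distance matrix")
    if np.any(X < 0):
        raise ValidationError("abundances must be non-negative")
    zero_rows = np.flatnonzero(X.sum(axis=1) == 0)
    if zero_rows.size:
        bad = [community.trap_ids[i] for i in zero_rows]
        raise ValidationError(
            f"Bray-Curtis undefined for empty trap(s) {bad}; drop them first"
        )
    d = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(labels=community.trap_ids, values=d)


def _anosim_r_from_ranks(
    ranks: np.ndarray, row: np.ndarray, col: np.ndarray, labels: np.ndarray,
    denom: float,
) -> float:
    within = labels[row] == labels[col]
    return (ranks[~within].mean() - ranks[within].mean()) / denom


def _prepare_groups(
    labels: np.ndarray, strict: bool, min_size: int = 2
) -> np.ndarray:
    """Boolean keep-mask after the small-group policy."""
    keep = np.ones(len(labels), dtype=bool)
    uniq, counts = np.unique(labels, return_counts=True)
    small = uniq[counts < min_size]
    if small.size:
        if strict:
            raise ValidationError(
                f"group(s) with fewer than {min_size} sites: {list(small)}"
            )
        logger.warning("dropping group(s) with <%d sites: %s", min_size, list(small))
        keep = ~np.isin(labels, small)
    return keep


def anosim(
    dm: DistanceMatrix,
    labels,
    n_perm: int = 9999,
    seed: int | None = None,
    strict: bool = True,
) -> AnosimResult:
    """One-way analysis of similarities (Clarke's ANOSIM).

    All n(n-1)/2 dissimilarities get mid-ranks (ties share their average
    rank); R contrasts the mean rank between groups with the mean rank
    within groups, scaled by n(n-1)/4 so R is in [-1, 1]. R near 0 means
    group labels do not structure the distances; R = 1 means every
    between-group distance exceeds every within-group one. Significance is
    by shuffling site labels ``n_perm`` times; the reported p uses the
    (1 + more-extreme)/(1 + n_perm) estimator, so p >= 1/(n_perm+1).

    Rank-based, hence invariant under any strictly monotone transform of
    the distances. Groups with a single site raise (``strict=True``) or are
    dropped with a warning.
    """
    labels = np.asarray(labels)
    if len(labels) != len(dm.labels):
        raise ValueError("labels length does not match distance matrix")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    keep = _prepare_groups(labels, strict=strict)
    if not keep.all():
        dm = dm.subset(keep)
        labels = labels[keep]
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValidationError("ANOSIM needs at least two groups with >=2 sites")

    n = len(labels)
    ranks = rankdata(dm.condensed())  # mid-ranks
    row, col = np.triu_indices(n, k=1)
    denom = n * (n - 1) / 4.0
    r_obs = _anosim_r_from_ranks(ranks, row, col, labels, denom)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _anosim_r_from_ranks(ranks, row, col, perm, denom) >= r_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return AnosimResult(R=float(r_obs), p=float(p), n_permutations=n_perm,
                        groups=[str(g) for g in uniq], n_sites=n)


def pairwise_anosim(
    dm: DistanceMatrix,
    labels,
    n_perm: int = 9999,
    seed: int | None = None,
    adjustment: str = "bonferroni",
    strict: bool = False,
) -> pd.DataFrame:
    """ANOSIM for every unordered pair of groups, with Bonferroni adjustment.

    Each pair is tested on its sub-matrix with an independent sub-seed
    split from ``seed``; adjusted p multiplies the raw p by the number of
    pairs actually tested (capped at 1). Pairs that fail preconditions are
    returned as flagged rows (``error`` column) rather than aborting the
    whole table.
    """
    if adjustment not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    labels = np.asarray(labels)
    keep = _prepare_groups(labels, strict=strict)
    dm_k, labels_k = dm, labels
    if not keep.all():
        dm_k, labels_k = dm.subset(keep), labels[keep]
    groups = sorted(np.unique(labels_k))
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    children = np.random.SeedSequence(seed).spawn(len(pairs))
    rows = []
    for (a, b), child in zip(pairs, children):
        mask = np.isin(labels_k, [a, b])
        sub = dm_k.subset(mask)
        try:
            res = anosim(sub, labels_k[mask], n_perm=n_perm,
                         seed=int(child.generate_state(1)[0] % 2**31))
            rows.append({"group_a": a, "group_b": b, "R": res.R,
                         "p_raw": res.p, "error": ""})
        except (ValidationError, ValueError) as exc:
            rows.append({"group_a": a, "group_b": b, "R": np.nan,
                         "p_raw": np.nan, "error": str(exc)})
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "R", "p_raw", "error"])
    n_tests = int(out["error"].eq("").sum())
    if adjustment == "bonferroni" and n_tests:
        out["p_adjusted"] = np.minimum(1.0, out["p_raw"] * n_tests)
    else:
        out["p_adjusted"] = out["p_raw"]
    return out[["group_a", "group_b", "R", "p_raw", "p_adjusted", "error"]]


def kendall_tau_b(x, y) -> CorrelationResult:
    """Kendall rank correlation (tau-b) with tie correction.

    tau_b = (C - D) / sqrt((n0 - n1)(n0 - n2)) where C/D count concordant
    and discordant pairs, n0 = n(n-1)/2 and n1, n2 are the tie terms of x
    and y. The p-value uses the normal approximation with tie-corrected
    variance, appropriate for the heavily tied INV/altitude data this
    serves.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    if len(x) < 3:
        raise ValidationError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("tau undefined when a vector is entirely tied")
    res = kendalltau(x, y, method="asymptotic")
    return CorrelationResult(tau_b=float(res.statistic), p=float(res.pvalue),
                             n=len(x))


def shapiro_wilk(x) -> NormalityResult:
    """Shapiro-Wilk W test of normality."""
    x = np.asarray(x, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValidationError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {len(x)}")
    if np.all(x == x[0]):
        raise ValidationError("W undefined for a constant sample")
    res = shapiro(x)
    return NormalityResult(W=float(res.statistic), p=float(res.pvalue))


def classified_subset(
    dm: DistanceMatrix, traps: pd.DataFrame
) -> tuple[DistanceMatrix, np.ndarray]:
    """Restrict a distance matrix to traps assigned a Natura 2000 habitat.

    Group comparisons contrast habitat types, so traps outside any
    classified habitat are excluded here (the INV itself keeps them).
    Returns the sub-matrix and the matching habitat label array.
    """
    habitats = traps.loc[dm.labels, "habitat"].to_numpy()
    keep = habitats != UNCLASSIFIED
    return dm.subset(keep), habitats[keep]
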