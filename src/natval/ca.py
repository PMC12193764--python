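"""Correspondence analysis of per-trap trait profiles.

The ordination is run on the traps x 9 matrix of trait components (FrT,
FrA, ArT for B, Z and E species), not on the species matrix: the question
is how traps differ in their *trait* make-up. CA decomposes the table's
chi-square residual structure (departure from row/column independence)
into orthogonal axes; each axis carries a share of the total inertia
(chi-square statistic / grand total).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ValidationError
from .inv import COMPONENT_ORDER

__all__ = ["CAResult", "profile_matrix", "correspondence_analysis"]

logger = logging.getLogger("natval")


@dataclass
class CAResult:
    principal_inertias: np.ndarray          # descending, one per retained axis
    percent_inertia: np.ndarray             # sums to 100 over retained axes
    row_coordinates: pd.DataFrame           # rows x axes, principal coordinates
    column_coordinates: pd.DataFrame        # cols x axes, principal coordinates
    total_inertia: float

    @property
    def n_axes(self) -> int:
        return len(self.principal_inertias)


def profile_matrix(profiles: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Trait-component matrix for CA, plus the all-zero rows to exclude.

    Column order is fixed to :data:`~natval.inv.COMPONENT_ORDER`. Traps
    whose nine components are all zero (no B/Z/E species at all, INV = 0)
    have no mass in the correspondence table and are flagged for exclusion.
    """
    M = profiles[COMPONENT_ORDER].copy()
    if len(M) < 2:
        raise ValidationError("need at least two profiles")
    zero = M.index[(M.to_numpy() == 0).all(axis=1)]
    if len(zero):
        logger.info("flagging %d all-zero profile(s) for CA exclusion: %s",
                    len(zero), list(zero))
    return M, list(zero)


def correspondence_analysis(
    M: pd.DataFrame, tol: float = 1e-12, coordinates: str = "principal"
) -> CAResult:
    """Classical CA via SVD of the standardized chi-square residuals.

    With correspondence matrix P = M / grand total, row masses r and column
    masses c, the residual matrix is S = D_r^{-1/2} (P - r c^T) D_c^{-1/2};
    its singular values sigma_k give principal inertias sigma_k^2, and
    principal coordinates are the mass-rescaled singular vectors scaled by
    sigma_k (``coordinates="standard"`` leaves out the sigma_k scaling).
    Axes with sigma^2 <= ``tol`` x total are dropped as numerical null
    space. Axis signs are fixed by making the largest-magnitude column
    loading on each axis positive, so outputs are reproducible despite the
    SVD's sign indeterminacy.
    """
    if coordinates not in ("principal", "standard"):
        raise ValueError(f"coordinates must be 'principal' or 'standard', got {coordinates!r}")
    Mv = M.to_numpy(dtype=float)
    if np.any(Mv < 0):
        raise ValidationError("CA requires a non-negative matrix")
    zero_rows = M.index[Mv.sum(axis=1) == 0].tolist()
    zero_cols = M.columns[Mv.sum(axis=0) == 0].tolist()
    if zero_rows or zero_cols:
        raise ValidationError(
            f"CA undefined with zero-mass rows {zero_rows} / columns {zero_cols}"
        )
    total = Mv.sum()
    P = Mv / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sig, Vt = np.linalg.svd(S, full_matrices=False)

    inertias = sig**2
    total_inertia = float(inertias.sum())
    if total_inertia <= tol:
        # exact independence: rank-0 residual, no axes
        empty = pd.DataFrame(index=M.index)
        return CAResult(np.array([]), np.array([]), empty,
                        pd.DataFrame(index=M.columns), 0.0)
    keep = inertias > tol * total_inertia
    U, sig, Vt, inertias = U[:, keep], sig[keep], Vt[keep], inertias[keep]

    scale = sig if coordinates == "principal" else 1.0
    F = (U / np.sqrt(r)[:, None]) * scale
    G = (Vt.T / np.sqrt(c)[:, None]) * scale
    for k in range(G.shape[1]):
        j = np.argmax(np.abs(G[:, k]))
        if G[j, k] < 0:
            G[:, k] *= -1
            F[:, k] *= -1

    axes = [f"axis{k + 1}" for k in range(len(sig))]
    return CAResult(
        principal_inertias=inertias,
        percent_inertia=100.0 * inertias / inertias.sum(),
        row_coordinates=pd.DataFrame(F, index=M.index, columns=axes),
        column_coordinates=pd.DataFrame(G, index=M.columns, columns=axes),
        total_inertia=total_inertia,
    )
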