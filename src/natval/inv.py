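"""Index of Natural Value (INV).

For each trap and each of the three conservation-relevant traits
(B brachypterous, Z specialized zoophagous, E Alpine endemic) three
fractions are computed:

* ``FrT_X`` -- trait species richness over trap species richness,
* ``FrA_X`` -- trait species richness in the trap over the number of
  species carrying trait X recorded anywhere in the study area,
* ``ArT_X`` -- summed activity density of trait-X species over the trap's
  total activity density.

INV is 100 times the arithmetic mean of these nine components, hence a
score in [0, 100]: high values flag communities rich in (and dominated by)
low-dispersal, trophically specialized and endemic species -- the ones most
exposed to habitat disturbance and climate change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import TRAITS, Dataset, ValidationError

__all__ = ["COMPONENT_ORDER", "area_trait_pool", "trait_profile",
           "trait_profiles", "inv_from_profile", "inv_table"]

#: Fixed, documented column order of the nine trait components.
COMPONENT_ORDER = [f"{part}_{t}" for t in TRAITS for part in ("FrT", "FrA", "ArT")]


def area_trait_pool(dataset: Dataset) -> dict[str, int]:
    """Number of species carrying each trait among species recorded in the area.

    The "study area" pool is the set of species caught in at least one
    retained trap (the recorded fauna), not an external regional checklist;
    species listed in the trait table but never caught do not count.
    """
    recorded = dataset.community.counts.columns[
        (dataset.community.counts > 0).any(axis=0)
    ]
    flags = dataset.traits.loc[recorded]
    return {t: int(flags[t].sum()) for t in TRAITS}


def trait_profile(
    ad_row: pd.Series,
    traits: pd.DataFrame,
    pools: dict[str, int],
) -> pd.Series:
    """Nine trait components for a single trap.

    ``ad_row`` is the trap's activity-density vector over species. A trait
    whose area pool is empty gets FrA 0 (no such species exist locally, so
    the trap cannot hold a share of them).
    """
    present = ad_row[ad_row > 0]
    if len(present) == 0:
        raise ValidationError("trait profile undefined for an empty trap")
    richness = len(present)
    total_ad = float(present.sum())
    flags = traits.loc[present.index]
    out = {}
    for t in TRAITS:
        has = flags[t]
        n_t = int(has.sum())
        out[f"FrT_{t}"] = n_t / richness
        out[f"FrA_{t}"] = n_t / pools[t] if pools[t] > 0 else 0.0
        out[f"ArT_{t}"] = float(present[has].sum()) / total_ad
    return pd.Series(out, index=COMPONENT_ORDER, dtype=float)


def inv_from_profile(profile: pd.Series | np.ndarray) -> float:
    """INV = 100 x mean of the nine trait components."""
    vals = np.asarray(profile, dtype=float)
    if vals.shape[-1] != 9:
        raise ValueError(f"expected 9 components, got {vals.shape}")
    if np.any(vals < 0) or np.any(vals > 1):
        raise ValidationError("profile components must lie in [0, 1]")
    return float(100.0 * vals.mean())


def trait_profiles(dataset: Dataset) -> pd.DataFrame:
    """Trait components for every trap, vectorized (traps x 9)."""
    ad = dataset.community.ad
    pools = area_trait_pool(dataset)
    presence = ad.to_numpy() > 0
    richness = presence.sum(axis=1)
    if np.any(richness == 0):
        empty = list(ad.index[richness == 0])
        raise ValidationError(f"empty trap(s) {empty}; run drop_empty_traps first")
    total_ad = ad.to_numpy().sum(axis=1)
    cols = {}
    for t in TRAITS:
        mask = dataset.traits.loc[ad.columns, t].to_numpy()
        n_t = (presence & mask).sum(axis=1)
        cols[f"FrT_{t}"] = n_t / richness
        cols[f"FrA_{t}"] = n_t / pools[t] if pools[t] > 0 else np.zeros(len(ad))
        cols[f"ArT_{t}"] = (ad.to_numpy() * mask).sum(axis=1) / total_ad
    out = pd.DataFrame(cols, index=ad.index)[COMPONENT_ORDER]
    out.insert(0, "richness", richness)
    return out


def inv_table(dataset: Dataset) -> pd.DataFrame:
    """Per-trap INV with its components and trap context.

    One row per retained trap (unclassified-habitat traps included; the
    index is defined trap-wise with no habitat condition). Columns:
    habitat, altitude_m, richness, the nine components, inv.
    """
    profiles = trait_profiles(dataset)
    inv = 100.0 * profiles[COMPONENT_ORDER].mean(axis=1)
    out = pd.concat(
        [dataset.traps.loc[profiles.index, ["habitat", "altitude_m"]], profiles],
        axis=1,
    )
    out["inv"] = inv
    return out


def write_inv_csv(inv_df: pd.DataFrame, path) -> None:
    inv_df.to_csv(path, float_format="%.6f")
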