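"""Habitat-level conservation-priority summaries and map attributes.

Per-trap INV values are aggregated to habitat level (count, mean, range,
altitude span) and joined onto habitat polygon features as map-ready
attributes: mean INV, a priority rank, and a color bin over the interval
spanned by the habitat means.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import UNCLASSIFIED, ValidationError

__all__ = ["habitat_summary", "priority_attributes"]

logger = logging.getLogger("natval")


def habitat_summary(
    inv_df: pd.DataFrame,
    traps: pd.DataFrame | None = None,
    area_ha: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-habitat trap count, INV mean/min/max and altitude range.

    ``inv_df`` is the per-trap table from :func:`natval.inv.inv_table`
    (must carry ``habitat``, ``altitude_m`` and ``inv`` columns).
    Unclassified traps are excluded; habitats are sorted by code.
    ``area_ha`` is an optional pass-through of cartographic habitat areas.
    """
    required = {"habitat", "altitude_m", "inv"}
    if not required <= set(inv_df.columns):
        raise ValidationError(f"inv table must carry columns {sorted(required)}")
    df = inv_df[inv_df["habitat"] != UNCLASSIFIED]
    if len(df) == 0:
        raise ValidationError("no classified traps to summarize")
    g = df.groupby("habitat")
    out = pd.DataFrame({
        "n_traps": g.size(),
        "inv_mean": g["inv"].mean(),
        "inv_min": g["inv"].min(),
        "inv_max": g["inv"].max(),
        "altitude_min": g["altitude_m"].min(),
        "altitude_max": g["altitude_m"].max(),
    }).sort_index()
    out.index.name = "habitat"
    if area_ha is not None:
        out["area_ha"] = pd.Series(area_ha).reindex(out.index)
    return out


def _priority_ranks(summaries: pd.DataFrame) -> pd.Series:
    """Rank 1 = highest mean INV; ties broken by habitat code (ascending)."""
    order = summaries.sort_index().sort_values("inv_mean", ascending=False,
                                               kind="stable")
    return pd.Series(np.arange(1, len(order) + 1), index=order.index)


def priority_attributes(
    summaries: pd.DataFrame,
    feature_collection: dict,
    habitat_property: str = "habitat",
    n_bins: int = 5,
) -> dict:
    """Annotate habitat polygons with mean INV, priority rank and color bin.

    ``feature_collection`` is a GeoJSON FeatureCollection whose features
    carry a habitat-code property. Returns a new FeatureCollection with
    ``inv_mean``, ``priority_rank`` and ``inv_bin`` added to each feature's
    properties (null for habitats without a summary, with a warning).
    Color-bin edges are ``n_bins`` equal intervals over
    [min of habitat means, max of habitat means]; the edges are recorded on
    the collection under ``"inv_bin_edges"``.
    """
    if feature_collection.get("type") != "FeatureCollection":
        raise ValidationError("expected a GeoJSON FeatureCollection")
    ranks = _priority_ranks(summaries)
    means = summaries["inv_mean"]
    lo, hi = (float(means.min()), float(means.max())) if len(means) else (0.0, 0.0)
    edges = np.linspace(lo, hi, n_bins + 1) if hi > lo else np.array([lo, hi])

    features = []
    for feat in feature_collection.get("features", []):
        feat = json.loads(json.dumps(feat))  # deep copy, JSON-safe
        props = feat.setdefault("properties", {})
        code = props.get(habitat_property)
        if code in summaries.index:
            mean = float(means[code])
            bin_idx = int(min(np.searchsorted(edges, mean, side="right") - 1,
                              len(edges) - 2)) if hi > lo else 0
            props.update(inv_mean=mean, priority_rank=int(ranks[code]),
                         inv_bin=bin_idx)
        else:
            logger.warning("polygon habitat %r has no summary; annotated null", code)
            props.update(inv_mean=None, priority_rank=None, inv_bin=None)
        features.append(feat)
    return {
        "type": "FeatureCollection",
        "inv_bin_edges": [float(e) for e in edges],
        "features": features,
    }


def write_priority_geojson(collection: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(collection, indent=2))
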