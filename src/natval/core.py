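"""Domain model and I/O for pitfall-trap catch data.

The pipeline works from three tables: catches (trap x species specimen
counts), trap metadata (plot, habitat code, altitude, days of activity) and
a species-trait table with three boolean flags per species:

* ``B`` -- brachypterous (wingless, low dispersal ability),
* ``Z`` -- specialized zoophagous (narrow prey specialization, e.g.
  snail feeders),
* ``E`` -- endemic of the European Alps.

The assembled :class:`Dataset` carries a trap x species community table in
two currencies: raw specimen counts and activity density (AD, specimens per
trap-day), the standard abundance measure for pitfall data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "ReferenceError_",
    "TRAITS",
    "UNCLASSIFIED",
    "DEFAULT_HABITAT_MERGE",
    "CommunityTable",
    "Dataset",
    "read_catch_table",
    "read_trap_table",
    "read_trait_table",
    "activity_density",
    "active_days_from_dates",
    "assemble_dataset",
    "drop_empty_traps",
    "write_dataset",
    "read_dataset",
]

logger = logging.getLogger("natval")

TRAITS = ("B", "Z", "E")

#: Habitat label for traps outside any classified habitat type.
UNCLASSIFIED = "unclassified"

#: Limestone cliffs (8210) and limestone pavements (8240) host very similar
#: ground-beetle communities and many traps sit on their boundary; they are
#: treated as one habitat unit throughout the analysis.
DEFAULT_HABITAT_MERGE = {"8210": "8210-8240", "8240": "8210-8240"}

ALTITUDE_RANGE = (0.0, 5000.0)


class SchemaError(ValueError):
    """An input table is missing required columns."""


class ValidationError(ValueError):
    """An input value violates a domain constraint."""


class ReferenceError_(ValueError):
    """A record refers to an entity absent from the dataset."""


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}; found {list(df.columns)}")


def read_catch_table(path: str | Path) -> pd.DataFrame:
    """Read a catches CSV (``trap_id,species,count``) and aggregate duplicates.

    Duplicate (trap, species) rows are summed, so partial counts (e.g. per
    collection round) may be listed on separate lines.

    Returns a DataFrame with columns ``trap_id, species, count`` sorted by
    trap then species.
    """
    df = pd.read_csv(path, dtype={"trap_id": str, "species": str})
    _require_columns(df, ("trap_id", "species", "count"), "catch table")
    if len(df) == 0:
        return df.loc[:, ["trap_id", "species", "count"]]
    if df["count"].isna().any():
        bad = df.index[df["count"].isna()].tolist()
        raise ValidationError(f"catch table: missing count in row(s) {bad}")
    counts = pd.to_numeric(df["count"])
    if (counts < 0).any():
        bad = df.index[counts < 0].tolist()
        raise ValidationError(f"catch table: negative count in row(s) {bad}")
    if (counts != counts.round()).any():
        bad = df.index[counts != counts.round()].tolist()
        raise ValidationError(f"catch table: non-integer count in row(s) {bad}")
    df = df.assign(count=counts.astype(np.int64))
    out = (
        df.groupby(["trap_id", "species"], as_index=False, sort=True)["count"]
        .sum()
    )
    return out


def read_trap_table(path: str | Path) -> pd.DataFrame:
    """Read a trap-metadata CSV into a DataFrame indexed by ``trap_id``.

    Expected columns: ``trap_id, plot_id, habitat, altitude_m, active_days``.
    An empty/missing habitat cell becomes :data:`UNCLASSIFIED`.
    """
    df = pd.read_csv(path, dtype={"trap_id": str, "plot_id": str, "habitat": str})
    _require_columns(df, ("trap_id", "plot_id", "habitat", "altitude_m", "active_days"), "trap table")
    if df["trap_id"].duplicated().any():
        dup = df.loc[df["trap_id"].duplicated(), "trap_id"].tolist()
        raise ValidationError(f"trap table: duplicate trap_id(s) {dup}")
    df = df.set_index("trap_id")
    df["habitat"] = df["habitat"].fillna(UNCLASSIFIED).replace("", UNCLASSIFIED)
    lo, hi = ALTITUDE_RANGE
    bad = df.index[(df["altitude_m"] < lo) | (df["altitude_m"] > hi)].tolist()
    if bad:
        raise ValidationError(f"trap table: altitude outside [{lo}, {hi}] for {bad}")
    if (df["active_days"] <= 0).any():
        bad = df.index[df["active_days"] <= 0].tolist()
        raise ValidationError(f"trap table: non-positive active_days for {bad}")
    return df


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read a species-trait CSV (``species,B,Z,E`` with 0/1 flags).

    Returns a boolean DataFrame indexed by species name.
    """
    df = pd.read_csv(path, dtype={"species": str})
    _require_columns(df, ("species",) + TRAITS, "trait table")
    if df["species"].duplicated().any():
        dup = df.loc[df["species"].duplicated(), "species"].tolist()
        raise ValidationError(f"trait table: duplicate species {dup}")
    df = df.set_index("species")
    for t in TRAITS:
        vals = set(pd.unique(df[t]))
        if not vals <= {0, 1, True, False}:
            raise ValidationError(f"trait table: column {t} must be 0/1, got {vals}")
    return df[list(TRAITS)].astype(bool)


def activity_density(count: float, active_days: float) -> float:
    """Specimens caught per day of trap activity (AD).

    AD is the abundance currency of pitfall trapping: raw catch scales with
    how long the trap was open, so counts are normalized by exposure.
    """
    if active_days <= 0:
        raise ValidationError(f"active_days must be > 0, got {active_days}")
    if count < 0:
        raise ValidationError(f"count must be >= 0, got {count}")
    return count / active_days


def active_days_from_dates(set_date: str, collect_date: str) -> int:
    """Day count between setting and collecting a trap.

    Inclusive of the set day, exclusive of the collection day (i.e. the
    plain date difference); the convention is isolated here so it can be
    swapped without touching the rest of the model.
    """
    delta = (pd.Timestamp(collect_date) - pd.Timestamp(set_date)).days
    if delta <= 0:
        raise ValidationError(
            f"collect date {collect_date} must be after set date {set_date}"
        )
    return int(delta)


@dataclass
class CommunityTable:
    """Trap x species abundance matrices.

    ``counts`` holds raw specimen counts; ``ad`` holds activity density,
    ``counts / active_days`` row-wise. Row order follows the trap table,
    column order is sorted species name; both are stable across runs.
    """

    counts: pd.DataFrame
    active_days: pd.Series

    def __post_init__(self) -> None:
        v = self.counts.to_numpy()
        if np.any(v < 0):
            raise ValidationError("counts must be non-negative")
        if np.all(v == np.floor(v)):  # keep float abundances usable as-is
            self.counts = self.counts.astype(np.int64)
        self.active_days = self.active_days.reindex(self.counts.index)

    @property
    def trap_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species_names(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def ad(self) -> pd.DataFrame:
        return self.counts.div(self.active_days, axis=0)


@dataclass
class Dataset:
    """Assembled, cross-validated inputs for the whole analysis."""

    traits: pd.DataFrame
    traps: pd.DataFrame
    community: CommunityTable
    habitat_merge_map: dict[str, str] = field(default_factory=dict)
    excluded_species: list[str] = field(default_factory=list)
    dropped_traps: list[str] = field(default_factory=list)

    def habitats(self, include_unclassified: bool = False) -> list[str]:
        codes = sorted(set(self.traps["habitat"]))
        if not include_unclassified:
            codes = [c for c in codes if c != UNCLASSIFIED]
        return codes


def assemble_dataset(
    traps: pd.DataFrame,
    catches: pd.DataFrame,
    traits: pd.DataFrame,
    habitat_merge_map: dict[str, str] | None = None,
    missing_trait_policy: str = "strict",
) -> Dataset:
    """Cross-validate the three tables and build the community matrix.

    ``habitat_merge_map`` rewrites raw habitat codes to analysis units
    (default merges limestone cliffs 8210 and pavements 8240). Species
    caught but absent from the trait table are handled per
    ``missing_trait_policy``:

    * ``"strict"`` -- raise (the default; silently guessing traits would
      bias the index invisibly);
    * ``"allfalse"`` -- keep the species with all trait flags false, with a
      logged warning;
    * ``"exclude"`` -- drop its catch records, with a logged warning;
      excluded names are recorded in ``Dataset.excluded_species``.
    """
    if habitat_merge_map is None:
        habitat_merge_map = dict(DEFAULT_HABITAT_MERGE)
    if missing_trait_policy not in ("strict", "allfalse", "exclude"):
        raise ValueError(f"unknown missing_trait_policy {missing_trait_policy!r}")

    traps = traps.copy()
    traps["habitat"] = traps["habitat"].map(lambda h: habitat_merge_map.get(h, h))

    unknown_traps = sorted(set(catches["trap_id"]) - set(traps.index))
    if unknown_traps:
        raise ReferenceError_(f"catch records refer to unknown trap(s) {unknown_traps}")

    traits = traits.copy()
    caught = sorted(set(catches["species"]))
    missing = [s for s in caught if s not in traits.index]
    excluded: list[str] = []
    if missing:
        if missing_trait_policy == "strict":
            raise ReferenceError_(
                f"species missing from trait table: {missing} "
                "(use missing_trait_policy='allfalse' or 'exclude' to proceed)"
            )
        if missing_trait_policy == "allfalse":
            logger.warning("treating %d species with no trait row as all-false: %s",
                           len(missing), missing)
            filler = pd.DataFrame(False, index=missing, columns=list(TRAITS))
            traits = pd.concat([traits, filler])
        else:
            logger.warning("excluding %d species with no trait row: %s",
                           len(missing), missing)
            catches = catches[~catches["species"].isin(missing)]
            excluded = missing

    counts = (
        catches.pivot_table(index="trap_id", columns="species", values="count",
                            aggfunc="sum", fill_value=0)
        .reindex(index=traps.index, fill_value=0)
    )
    counts = counts[sorted(counts.columns)]
    counts.columns.name = None
    counts.index.name = "trap_id"

    community = CommunityTable(counts=counts, active_days=traps["active_days"])
    return Dataset(
        traits=traits,
        traps=traps,
        community=community,
        habitat_merge_map=dict(habitat_merge_map),
        excluded_species=excluded,
    )


def drop_empty_traps(dataset: Dataset) -> tuple[Dataset, list[str]]:
    """Remove traps that caught no beetles at all.

    A zero catch carries no community information (its AD vector is
    undefined as a composition), so such traps are excluded from every
    downstream statistic. Idempotent. Returns the reduced dataset and the
    list of dropped trap ids.
    """
    totals = dataset.community.counts.sum(axis=1)
    dropped = list(totals.index[totals == 0])
    if dropped:
        logger.info("dropping %d empty trap(s): %s", len(dropped), dropped)
    keep = totals.index[totals > 0]
    community = CommunityTable(
        counts=dataset.community.counts.loc[keep],
        active_days=dataset.community.active_days.loc[keep],
    )
    return (
        Dataset(
            traits=dataset.traits,
            traps=dataset.traps.loc[keep],
            community=community,
            habitat_merge_map=dataset.habitat_merge_map,
            excluded_species=list(dataset.excluded_species),
            dropped_traps=list(dataset.dropped_traps) + dropped,
        ),
        dropped,
    )


def write_dataset(dataset: Dataset, outdir: str | Path) -> None:
    """Serialize a dataset as the three input CSVs plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = dataset.community.counts
    long = counts.stack().rename("count").reset_index()
    long.columns = ["trap_id", "species", "count"]
    # zero rows are kept so the community frame (incl. all-zero species
    # columns) survives a round trip exactly
    long.to_csv(outdir / "catches.csv", index=False)
    traps = dataset.traps.reset_index()
    traps.to_csv(outdir / "traps.csv", index=False)
    traits = dataset.traits.astype(int).reset_index()
    traits.columns = ["species"] + list(TRAITS)
    traits.to_csv(outdir / "traits.csv", index=False)
    manifest = {
        "habitat_merge_map": dataset.habitat_merge_map,
        "excluded_species": dataset.excluded_species,
        "dropped_traps": dataset.dropped_traps,
        "n_traps": len(dataset.traps),
        "n_species": len(counts.columns),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_dataset(indir: str | Path, missing_trait_policy: str = "strict") -> Dataset:
    """Rebuild a dataset from a directory written by :func:`write_dataset`.

    Habitat codes on disk are already merged, so no merge map is reapplied.
    """
    indir = Path(indir)
    traps = read_trap_table(indir / "traps.csv")
    catches = read_catch_table(indir / "catches.csv")
    traits = read_trait_table(indir / "traits.csv")
    ds = assemble_dataset(traps, catches, traits, habitat_merge_map={},
                          missing_trait_policy=missing_trait_policy)
    manifest_path = indir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        ds.habitat_merge_map = manifest.get("habitat_merge_map", {})
        ds.dropped_traps = manifest.get("dropped_traps", [])
    return ds
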