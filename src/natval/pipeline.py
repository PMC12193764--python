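"""End-to-end analysis: from the three input tables to the report bundle.

Stage order mirrors the study design: assemble and validate the dataset,
drop empty traps, compute per-trap INV, test the INV-altitude association
(Kendall tau-b, after a Shapiro-Wilk normality check motivating the rank
test), ordinate the trait profiles (CA), compare habitat communities
(global + pairwise ANOSIM on Bray-Curtis distances), identify indicator
species (IndVal), and summarize habitats for prioritization, optionally
joining the summaries onto habitat polygons.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import ca as ca_mod
from . import indval as indval_mod
from . import inv as inv_mod
from . import prioritize as prio_mod
from . import stats as stats_mod
from .core import (Dataset, assemble_dataset, drop_empty_traps,
                   read_catch_table, read_trait_table, read_trap_table,
                   DEFAULT_HABITAT_MERGE)

logger = logging.getLogger("natval")

#: Stage names used for seed splitting, in fixed order.
SEEDED_STAGES = ("anosim", "pairwise_anosim", "indval")


@dataclass
class RunConfig:
    catches: str | Path
    traps: str | Path
    traits: str | Path
    outdir: str | Path
    polygons: str | Path | None = None
    habitat_merge_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_HABITAT_MERGE))
    n_perm: int = 9999
    seed: int = 0
    abundance_currency: str = "ad"
    missing_trait_policy: str = "strict"
    include_unclassified_in_ca: bool = True

    def validate(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.abundance_currency not in ("ad", "counts"):
            raise ValueError("abundance_currency must be 'ad' or 'counts'")
        for p in (self.catches, self.traps, self.traits):
            if not Path(p).exists():
                raise FileNotFoundError(p)


def stage_seeds(seed: int) -> dict[str, int]:
    """Split one run seed into independent per-stage seeds.

    Children are spawned from ``numpy.random.SeedSequence(seed)`` in the
    fixed order of :data:`SEEDED_STAGES` and reduced mod 2^31, so a stage
    can be rerun in isolation with an identical stream.
    """
    children = np.random.SeedSequence(seed).spawn(len(SEEDED_STAGES))
    return {name: int(c.generate_state(1)[0] % 2**31)
            for name, c in zip(SEEDED_STAGES, children)}


def run(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns a summary dict (also written as ``summary.json``). Any stage
    failure writes a FAILED marker naming the stage and re-raises, keeping
    the outputs of completed stages on disk.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    warnings: list[str] = []
    stage = "read_inputs"
    try:
        traps = read_trap_table(config.traps)
        catches = read_catch_table(config.catches)
        traits = read_trait_table(config.traits)

        stage = "assemble"
        ds = assemble_dataset(traps, catches, traits,
                              habitat_merge_map=config.habitat_merge_map,
                              missing_trait_policy=config.missing_trait_policy)
        if ds.excluded_species:
            warnings.append(f"excluded species without traits: {ds.excluded_species}")

        stage = "drop_empty_traps"
        ds, dropped = drop_empty_traps(ds)

        stage = "inv"
        inv_df = inv_mod.inv_table(ds)
        inv_mod.write_inv_csv(inv_df, outdir / "inv.csv")

        stage = "inv_altitude_tests"
        sw = stats_mod.shapiro_wilk(inv_df["inv"])
        kt = stats_mod.kendall_tau_b(inv_df["altitude_m"], inv_df["inv"])

        stage = "ca"
        profiles = inv_df
        if not config.include_unclassified_in_ca:
            profiles = inv_df[inv_df["habitat"] != "unclassified"]
        M, zero_rows = ca_mod.profile_matrix(profiles)
        if zero_rows:
            warnings.append(f"traps excluded from CA (all-zero profile): {zero_rows}")
        ca_res = ca_mod.correspondence_analysis(M.drop(index=zero_rows))
        ca_res.row_coordinates.to_csv(outdir / "ca_rows.csv",
                                      index_label="trap_id")
        ca_res.column_coordinates.to_csv(outdir / "ca_cols.csv",
                                         index_label="component")
        (outdir / "ca_summary.json").write_text(json.dumps({
            "total_inertia": ca_res.total_inertia,
            "principal_inertias": ca_res.principal_inertias.tolist(),
            "percent_inertia": ca_res.percent_inertia.tolist(),
            "excluded_rows": zero_rows,
        }, indent=2))

        stage = "anosim"
        dm = stats_mod.bray_curtis_matrix(ds.community,
                                          value_field=config.abundance_currency)
        dm_cls, habs = stats_mod.classified_subset(dm, ds.traps)
        global_res = stats_mod.anosim(dm_cls, habs, n_perm=config.n_perm,
                                      seed=seeds["anosim"], strict=False)
        stage = "pairwise_anosim"
        pairwise = stats_mod.pairwise_anosim(dm_cls, habs, n_perm=config.n_perm,
                                             seed=seeds["pairwise_anosim"])
        (outdir / "anosim.json").write_text(json.dumps({
            "global": asdict(global_res),
            "pairwise": pairwise.to_dict(orient="records"),
            "n_perm": config.n_perm,
            "seed": seeds["anosim"],
            "pairwise_seed": seeds["pairwise_anosim"],
            "abundance_currency": config.abundance_currency,
        }, indent=2))

        stage = "indval"
        keep = ds.traps.loc[ds.community.trap_ids, "habitat"] != "unclassified"
        from .core import CommunityTable
        comm_cls = CommunityTable(
            counts=ds.community.counts.loc[keep],
            active_days=ds.community.active_days.loc[keep],
        )
        labels_cls = ds.traps.loc[comm_cls.trap_ids, "habitat"].to_numpy()
        indval_df = indval_mod.indval_test(
            comm_cls, labels_cls, n_perm=config.n_perm, seed=seeds["indval"],
            value_field=config.abundance_currency)
        indval_df.to_csv(outdir / "indval.csv", index_label="species",
                         float_format="%.6f")

        stage = "habitat_summary"
        summary_df = prio_mod.habitat_summary(inv_df, ds.traps)
        summary_df.to_csv(outdir / "habitat_summary.csv", float_format="%.6f")

        geojson_written = False
        if config.polygons is not None:
            stage = "priority_map"
            fc = json.loads(Path(config.polygons).read_text())
            annotated = prio_mod.priority_attributes(summary_df, fc)
            prio_mod.write_priority_geojson(annotated, outdir / "priority.geojson")
            geojson_written = True

        stage = "manifest"
        summary = {
            "n_traps_input": int(len(traps)),
            "n_traps_retained": int(len(ds.traps)),
            "dropped_traps": dropped,
            "n_species": int(len(ds.community.species_names)),
            "inv": {"min": float(inv_df["inv"].min()),
                    "max": float(inv_df["inv"].max()),
                    "mean": float(inv_df["inv"].mean())},
            "shapiro_wilk": asdict(sw),
            "kendall_inv_altitude": asdict(kt),
            "ca_percent_inertia": ca_res.percent_inertia.tolist(),
            "anosim_global": asdict(global_res),
            "n_pairwise_tests": int(pairwise["error"].eq("").sum()),
            "significant_indicators": indval_df.index[
                indval_df["p_adjusted"] < 0.05].tolist(),
            "priority_geojson": geojson_written,
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
        manifest = {
            "natval_version": __version__,
            "config": {k: (str(v) if isinstance(v, Path) else v)
                       for k, v in asdict(config).items()},
            "stage_seeds": seeds,
            "dropped_traps": dropped,
            "warnings": warnings,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return summary
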