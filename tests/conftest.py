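import numpy as np
import pandas as pd
import pytest

from natval.core import CommunityTable, assemble_dataset, drop_empty_traps
from natval.synthetic import generate, preset


def make_dataset(counts: dict, traps: dict, traits: dict,
                 merge_map=None) -> "Dataset":
    """Build a Dataset from plain dicts.

    counts: {trap_id: {species: count}}, traps: {trap_id: (plot, habitat,
    altitude_m, active_days)}, traits: {species: "BZE" subset string}.
    """
    trap_rows = [
        {"trap_id": t, "plot_id": p, "habitat": h, "altitude_m": a,
         "active_days": d}
        for t, (p, h, a, d) in traps.items()
    ]
    traps_df = pd.DataFrame(trap_rows).set_index("trap_id")
    catch_rows = [
        {"trap_id": t, "species": s, "count": c}
        for t, spp in counts.items() for s, c in spp.items()
    ]
    catches_df = pd.DataFrame(catch_rows,
                              columns=["trap_id", "species", "count"])
    traits_df = pd.DataFrame(
        {"B": [("B" in f) for f in traits.values()],
         "Z": [("Z" in f) for f in traits.values()],
         "E": [("E" in f) for f in traits.values()]},
        index=pd.Index(list(traits.keys()), name="species"),
    )
    return assemble_dataset(traps_df, catches_df, traits_df,
                            habitat_merge_map=merge_map or {})


def community_from_matrix(X, active_days=1.0) -> CommunityTable:
    X = np.asarray(X)
    counts = pd.DataFrame(X, index=[f"T{i}" for i in range(X.shape[0])],
                          columns=[f"sp{j}" for j in range(X.shape[1])])
    return CommunityTable(counts=counts,
                          active_days=pd.Series(active_days, index=counts.index))


@pytest.fixture(scope="session")
def gradient_dataset():
    """One realization of the default field-campaign emulation, empties dropped."""
    ds, truth = generate(preset("gradient", seed=11))
    ds, dropped = drop_empty_traps(ds)
    return ds, truth, dropped


@pytest.fixture
def two_species_trap():
    """The hand-worked INV example: one trap, a B species and a B+E species."""
    return make_dataset(
        counts={"T1": {"sp1": 45, "sp2": 45}},
        traps={"T1": ("P1", "6170", 2000.0, 90)},
        traits={"sp1": "B", "sp2": "BE"},
    )
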