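"""Simulation experiments: permutation-test calibration and effect recovery.

These experiments validate the inferential machinery against the synthetic
generator's known truth: under the exchangeable ``null`` preset the
permutation tests must reject at their nominal rate, and planted effects
(the ``gradient`` altitude trend, the ``indicator`` habitat specialist)
must be recovered reliably. They power both the test suite and the
acceptance script.
"""

from __future__ import annotations

import numpy as np

from .core import drop_empty_traps
from .indval import indval_observed, indval_test
from .inv import inv_table
from .stats import anosim, bray_curtis_matrix, kendall_tau_b
from .synthetic import generate, preset

__all__ = ["anosim_type1_error", "indval_type1_error",
           "gradient_recovery", "indicator_recovery"]


def _sim_seeds(seed: int, n: int) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def _null_dataset(seed: int, n_habitats: int, traps_per_habitat: int,
                  n_species: int):
    cfg = preset("null", seed=seed, n_habitats=n_habitats,
                 traps_per_habitat=traps_per_habitat, n_species=n_species)
    ds, _ = generate(cfg)
    ds, _ = drop_empty_traps(ds)
    return ds


def anosim_type1_error(
    n_sims: int = 500, n_perm: int = 199, alpha: float = 0.05, seed: int = 0,
    n_habitats: int = 2, traps_per_habitat: int = 8, n_species: int = 12,
) -> float:
    """Fraction of null-preset datasets where global ANOSIM rejects at alpha.

    Habitats are exchangeable by construction, so the fraction estimates
    the test's type-I error and should sit near alpha.
    """
    rejections = 0
    for s in _sim_seeds(seed, n_sims):
        ds = _null_dataset(s, n_habitats, traps_per_habitat, n_species)
        dm = bray_curtis_matrix(ds.community)
        labels = ds.traps["habitat"].to_numpy()
        res = anosim(dm, labels, n_perm=n_perm, seed=s, strict=False)
        rejections += res.p <= alpha
    return rejections / n_sims


def indval_type1_error(
    n_sims: int = 500, n_perm: int = 199, alpha: float = 0.05, seed: int = 0,
    n_habitats: int = 2, traps_per_habitat: int = 8, n_species: int = 12,
) -> float:
    """Type-I error of the IndVal permutation test for a neutral species.

    Every species is neutral under the null preset; the most prevalent one
    is scored (rare species have a coarse, conservative null distribution
    that says little about calibration).
    """
    rejections = 0
    for s in _sim_seeds(seed, n_sims):
        ds = _null_dataset(s, n_habitats, traps_per_habitat, n_species)
        labels = ds.traps["habitat"].to_numpy()
        out = indval_test(ds.community, labels, n_perm=n_perm, seed=s,
                          adjustment="none")
        prevalence = (ds.community.counts > 0).sum(axis=0)
        target = prevalence.idxmax()
        rejections += out.loc[target, "p_raw"] <= alpha
    return rejections / n_sims


def gradient_recovery(
    n_seeds: int = 100, seed: int = 0, p_threshold: float = 0.01
) -> float:
    """Fraction of gradient-preset realizations with a detected altitude trend.

    Success = Kendall tau between per-trap INV and altitude positive with
    p below ``p_threshold``, mirroring the planted positive effect of
    altitude on the catch rates of specialized and endemic species.
    """
    hits = 0
    for s in _sim_seeds(seed, n_seeds):
        ds, _ = generate(preset("gradient", seed=s))
        ds, _ = drop_empty_traps(ds)
        inv_df = inv_table(ds)
        res = kendall_tau_b(inv_df["altitude_m"], inv_df["inv"])
        hits += (res.tau_b > 0) and (res.p < p_threshold)
    return hits / n_seeds


def indicator_recovery(n_seeds: int = 100, seed: int = 0) -> float:
    """Fraction of indicator-preset realizations where the planted species
    is the top observed IndVal hit in its planted habitat."""
    hits = 0
    for s in _sim_seeds(seed, n_seeds):
        ds, truth = generate(preset("indicator", seed=s))
        ds, _ = drop_empty_traps(ds)
        labels = ds.traps["habitat"].to_numpy()
        obs = indval_observed(ds.community, labels)
        top = obs["indval"].idxmax()
        planted = truth["planted_indicator"]
        hits += (top == planted["species"]
                 and obs.loc[top, "best_group"] == planted["habitat"])
    return hits / n_seeds
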