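"""Spatially separated subsamples of focal plots.

Observations from nearby inventory plots are not independent; regressing
diversity on terrain over all of them inflates the effective sample size
(pseudoreplication). The remedy used here is repeated spatial thinning:
each replicate shuffles the plot order with its own seeded generator and
greedily accepts every plot at least ``min_separation_km`` from all plots
accepted before it. The accepted set is a maximal packing for that scan
order, and replicate-to-replicate randomness feeds the percentile
confidence intervals downstream.

Replicate i draws its generator from ``SeedSequence(master_seed,
spawn_key=(i,))``, a counter-based split: replicates are individually
reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geodiversity import haversine_km
from .io import PlotCommunity


@dataclass
class SubsampleReplicate:
    replicate_index: int
    seed: int
    plot_ids: list[str] = field(default_factory=list)  # in accepted order
    min_separation_km: float = 0.0


def pairwise_distance(p1: PlotCommunity, p2: PlotCommunity,
                      crs_mode: str = "projected") -> float:
    """Distance between two plots in km (Euclidean/1000 or haversine)."""
    if crs_mode == "projected":
        return float(np.hypot(p1.x - p2.x, p1.y - p2.y) / 1000.0)
    if crs_mode == "geographic":
        return float(haversine_km(p1.x, p1.y, p2.x, p2.y))
    raise ValueError(f"unknown crs_mode {crs_mode!r}")


def _distance_matrix_km(plots: list[PlotCommunity], crs_mode: str) -> np.ndarray:
    x = np.array([p.x for p in plots])
    y = np.array([p.y for p in plots])
    if crs_mode == "projected":
        return np.hypot(x[:, None] - x[None, :], y[:, None] - y[None, :]) / 1000.0
    return np.asarray(haversine_km(x[:, None], y[:, None], x[None, :], y[None, :]))


def draw_subsample(plots: list[PlotCommunity], min_separation_km: float,
                   seed, replicate_index: int = 0,
                   crs_mode: str = "projected",
                   _dist: np.ndarray | None = None) -> SubsampleReplicate:
    """One spatially thinned subsample: seeded shuffle + greedy maximal packing.

    Every accepted pair is >= ``min_separation_km`` apart and no rejected
    plot could be added afterwards. ``seed`` may be an int or a
    ``numpy.random.SeedSequence``.
    """
    if not plots:
        raise ValueError("cannot subsample an empty plot list")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.Generator(np.random.PCG64(ss))
    order = rng.permutation(len(plots))
    dist = _dist if _dist is not None else _distance_matrix_km(plots, crs_mode)
    accepted: list[int] = []
    for idx in order:
        if all(dist[idx, a] >= min_separation_km for a in accepted):
            accepted.append(int(idx))
    seed_int = int(ss.generate_state(1, dtype=np.uint32)[0])
    return SubsampleReplicate(
        replicate_index=replicate_index,
        seed=seed_int,
        plot_ids=[plots[i].plot_id for i in accepted],
        min_separation_km=min_separation_km,
    )


def replicate_subsamples(plots: list[PlotCommunity], min_separation_km: float,
                         n_replicates: int, master_seed: int,
                         crs_mode: str = "projected") -> list[SubsampleReplicate]:
    """n independent, individually reproducible thinning replicates.

    Replicate i is fully determined by (master_seed, i); computing any
    subset, in any order, yields identical replicates.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    dist = _distance_matrix_km(plots, crs_mode)
    out = []
    for i in range(n_replicates):
        ss = np.random.SeedSequence(master_seed, spawn_key=(i,))
        out.append(draw_subsample(plots, min_separation_km, ss, replicate_index=i,
                                  crs_mode=crs_mode, _dist=dist))
    return out
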