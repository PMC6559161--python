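"""Abundance-weighted taxonomic diversity of tree communities.

Per-plot diversity is the effective species number (Hill number of order
q=1): ``D = exp(H')`` with ``H' = -sum p_i ln p_i`` on basal-area shares
p_i. For a neighbourhood of plots within a radius of a focal plot:

* alpha — the median of the member plots' effective species numbers,
* beta  — the mean Bray-Curtis dissimilarity over all unordered plot
  pairs, in [0, 1] (undefined for a single-plot neighbourhood),
* gamma — the effective species number of the pooled community obtained
  by summing basal areas species-wise across member plots.

The Bray-Curtis index can be computed on raw basal areas (default,
abundance-weighted across plots) or on within-plot proportional
abundances (``variant="proportion"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import PlotCommunity


@dataclass
class NeighborhoodCommunity:
    """All plots within ``radius_km`` of a focal plot, focal included."""

    focal_plot_id: str
    members: list[PlotCommunity]
    radius_km: float

    def __post_init__(self) -> None:
        ids = [p.plot_id for p in self.members]
        if self.focal_plot_id not in ids:
            raise ValueError(f"focal plot {self.focal_plot_id!r} missing from members")


def effective_species_number(abundances) -> float:
    """Hill number of order 1: exp of the Shannon entropy of the shares.

    Accepts a species->abundance mapping or an array of nonnegative
    abundances; zero-abundance species contribute nothing. Equal shares
    across S species give exactly S; a single species gives 1.
    """
    if isinstance(abundances, dict):
        a = np.array(list(abundances.values()), dtype=float)
    else:
        a = np.asarray(abundances, dtype=float)
    if np.any(a < 0):
        raise ValueError("abundances must be nonnegative")
    total = a.sum()
    if total <= 0:
        raise ValueError("effective species number undefined for all-zero abundances")
    p = a[a > 0] / total
    return float(np.exp(-np.sum(p * np.log(p))))


def pairwise_dissimilarity(a, b, variant: str = "basal_area") -> float:
    """Bray-Curtis dissimilarity between two communities, in [0, 1].

    ``d = 1 - 2 sum_i min(a_i, b_i) / (sum a + sum b)`` after aligning
    species. 0 iff identical vectors, 1 iff disjoint support. With
    ``variant="proportion"`` each community is first normalised to
    within-plot shares.
    """
    if isinstance(a, dict) or isinstance(b, dict):
        species = sorted(set(a) | set(b))
        av = np.array([a.get(s, 0.0) for s in species], dtype=float)
        bv = np.array([b.get(s, 0.0) for s in species], dtype=float)
    else:
        av, bv = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if av.sum() <= 0 or bv.sum() <= 0:
        raise ValueError("Bray-Curtis undefined for a zero-total community")
    if variant == "proportion":
        av, bv = av / av.sum(), bv / bv.sum()
    elif variant != "basal_area":
        raise ValueError(f"unknown dissimilarity variant {variant!r}")
    return float(1.0 - 2.0 * np.minimum(av, bv).sum() / (av.sum() + bv.sum()))


def _abundance_matrix(plots: list[PlotCommunity]) -> tuple[np.ndarray, list[str]]:
    """Dense plot x species basal-area matrix over the union species set."""
    species = sorted({s for p in plots for s in p.abundances})
    mat = np.zeros((len(plots), len(species)))
    index = {s: k for k, s in enumerate(species)}
    for i, p in enumerate(plots):
        for s, ba in p.abundances.items():
            mat[i, index[s]] = ba
    return mat, species


def alpha_diversity(neighborhood: NeighborhoodCommunity) -> float:
    """Median per-plot effective species number across member plots."""
    if not neighborhood.members:
        raise ValueError("alpha diversity undefined for an empty neighbourhood")
    d = [effective_species_number(p.abundances) for p in neighborhood.members]
    return float(np.median(d))


def beta_diversity(neighborhood: NeighborhoodCommunity,
                   variant: str = "basal_area") -> float:
    """Mean pairwise Bray-Curtis over all C(m,2) plot pairs; NaN when m = 1."""
    m = len(neighborhood.members)
    if m == 0:
        raise ValueError("beta diversity undefined for an empty neighbourhood")
    if m == 1:
        return float("nan")
    mat, _ = _abundance_matrix(neighborhood.members)
    if variant == "proportion":
        mat = mat / mat.sum(axis=1, keepdims=True)
    from scipy.spatial.distance import pdist

    return float(pdist(mat, metric="braycurtis").mean())


def gamma_diversity(neighborhood: NeighborhoodCommunity) -> float:
    """Effective species number of all member plots pooled as one community."""
    if not neighborhood.members:
        raise ValueError("gamma diversity undefined for an empty neighbourhood")
    mat, _ = _abundance_matrix(neighborhood.members)
    return effective_species_number(mat.sum(axis=0))
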