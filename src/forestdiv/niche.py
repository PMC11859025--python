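"""Niche width and niche overlap on subplot resource states.

The resource states are the plot's 10 m x 10 m subplots: a species'
resource-use vector is how its stems distribute over subplots (counts) or
which subplots it occupies (0/1). Niche width is Levins' B = 1 / sum p_k^2,
the effective number of subplots used (1 = a single subplot, K = perfectly
even use of all K). Niche overlap between two species is Pianka's index,
the cosine similarity of their proportional-use vectors, in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import CensusTable


@dataclass
class ResourceUseMatrix:
    """Species x resource-state (subplot) use matrix.

    ``counts`` rows are species, columns subplot indices; entries are
    non-negative integers (stem counts, or 0/1 occupancy). Analyzed rows
    must have a positive sum; proportions are derived on demand.
    """

    counts: pd.DataFrame
    mode: str = "counts"

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("resource-use entries must be non-negative")

    @property
    def n_states(self) -> int:
        return self.counts.shape[1]

    def proportions(self) -> pd.DataFrame:
        sums = self.counts.sum(axis=1)
        if (sums == 0).any():
            bad = sums.index[sums == 0][0]
            raise ValueError(f"species {bad!r} has an all-zero resource row")
        return self.counts.div(sums, axis=0)


def build_resource_matrix(
    census: CensusTable, subplot_size: float | None = None, mode: str = "counts",
) -> ResourceUseMatrix:
    """Tabulate stems (mode="counts") or occupancy (mode="occupancy") of
    every species over the subplot grid."""
    if mode not in ("counts", "occupancy"):
        raise ValueError(f"unknown mode {mode!r}")
    win = census.window
    if subplot_size is not None and subplot_size != win.subplot_size:
        from .core_data import PlotWindow

        win = PlotWindow(win.width, win.height, subplot_size)
    sub = win.subplot_index(census.data["x"], census.data["y"])
    tab = pd.crosstab(census.data["species"], pd.Series(sub, name="subplot"))
    tab = tab.reindex(columns=range(win.n_subplots), fill_value=0).sort_index()
    if mode == "occupancy":
        tab = (tab > 0).astype(int)
    return ResourceUseMatrix(tab, mode=mode)


def levins_width(row) -> float:
    """Levins' niche breadth B = 1 / sum p_k^2 for one use vector."""
    r = np.asarray(row, dtype=float)
    total = r.sum()
    if total <= 0:
        raise ValueError("resource row sums to zero")
    p = r / total
    return float(1.0 / np.sum(p * p))


def levins_width_standardized(row, n_states: int | None = None) -> float:
    """B_A = (B - 1)/(K - 1), rescaled to [0, 1]."""
    r = np.asarray(row, dtype=float)
    k = n_states if n_states is not None else r.size
    return (levins_width(r) - 1.0) / (k - 1.0)


def niche_widths(rum: ResourceUseMatrix, standardized: bool = False) -> pd.Series:
    """Levins width per species of a resource-use matrix."""
    widths = rum.counts.apply(levins_width, axis=1)
    if standardized:
        widths = (widths - 1.0) / (rum.n_states - 1.0)
    return widths.rename("levins_B_std" if standardized else "levins_B")


def pianka_overlap(row_i, row_j) -> float:
    """Pianka's niche overlap O = sum p_i p_j / sqrt(sum p_i^2 sum p_j^2)."""
    pi = np.asarray(row_i, dtype=float)
    pj = np.asarray(row_j, dtype=float)
    if pi.sum() <= 0 or pj.sum() <= 0:
        raise ValueError("resource rows must be nonzero")
    pi = pi / pi.sum()
    pj = pj / pj.sum()
    return float(np.dot(pi, pj) / np.sqrt(np.dot(pi, pi) * np.dot(pj, pj)))


def schoener_overlap(row_i, row_j) -> float:
    """Schoener's overlap 1 - 0.5 * sum |p_i - p_j| (alternative index)."""
    pi = np.asarray(row_i, dtype=float)
    pj = np.asarray(row_j, dtype=float)
    if pi.sum() <= 0 or pj.sum() <= 0:
        raise ValueError("resource rows must be nonzero")
    pi = pi / pi.sum()
    pj = pj / pj.sum()
    return float(1.0 - 0.5 * np.abs(pi - pj).sum())


_OVERLAP_FN = {"pianka": pianka_overlap, "schoener": schoener_overlap}


def overlap_matrix(rum: ResourceUseMatrix, method: str = "pianka") -> pd.DataFrame:
    """Symmetric species x species overlap matrix with unit diagonal."""
    fn = _OVERLAP_FN[method]
    p = rum.proportions().to_numpy()
    n = p.shape[0]
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = fn(p[i], p[j])
    sp = rum.counts.index
    return pd.DataFrame(out, index=sp, columns=sp)


@dataclass
class OverlapDistribution:
    species: list
    values: np.ndarray
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    max_overlap: float
    method: str


def overlap_distribution(
    rum: ResourceUseMatrix, top_k: int = 25, abundances: pd.Series | None = None,
    method: str = "pianka", n_bins: int = 10,
) -> OverlapDistribution:
    """Distribution of pairwise overlaps among the top-k species.

    Ranking is by ``abundances`` when given (total stems is the natural
    choice for an occupancy matrix), else by matrix row sums; ties broken
    by species code. With S species the histogram summarizes
    min(top_k, S)·(min(top_k, S) - 1)/2 off-diagonal values on [0, 1].
    """
    if rum.counts.shape[0] < 2:
        raise ValueError("need at least 2 species")
    rank = abundances.reindex(rum.counts.index) if abundances is not None \
        else rum.counts.sum(axis=1)
    order = (
        rank.rename("rank").rename_axis("species").reset_index()
        .sort_values(["rank", "species"], ascending=[False, True], kind="stable")
    )
    top = list(order["species"].iloc[: min(top_k, len(order))])
    sub = ResourceUseMatrix(rum.counts.loc[top], mode=rum.mode)
    mat = overlap_matrix(sub, method=method)
    iu = np.triu_indices(len(top), k=1)
    vals = mat.to_numpy()[iu]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    return OverlapDistribution(
        species=top, values=vals, bin_edges=edges, bin_counts=counts,
        max_overlap=float(vals.max()), method=method,
    )


def compare_widths(widths_a, widths_b):
    """Two-sided Mann-Whitney U comparison of two niche-width samples.

    Returns the scipy result (statistic, pvalue).
    """
    a = np.asarray(widths_a, dtype=float)
    b = np.asarray(widths_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 species per sample")
    return stats.mannwhitneyu(a, b, alternative="two-sided")


def niche_analysis(census: CensusTable, top_k: int = 25, method: str = "pianka"):
    """The standard plot-level niche summary: Levins width for all species
    on stem counts, and the top-k overlap distribution on subplot
    occupancy (ranked by total abundance)."""
    widths = niche_widths(build_resource_matrix(census, mode="counts"))
    occ = build_resource_matrix(census, mode="occupancy")
    dist = overlap_distribution(
        occ, top_k=top_k, abundances=census.abundances(), method=method
    )
    return widths, dist
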