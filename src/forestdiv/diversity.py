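"""Importance values, rank-abundance curves, and taxon accumulation curves.

Importance value (IV) of a species is the sum of its relative frequency
(share of occupied subplots), relative dominance (share of basal area) and
relative density (share of stems), each in percent, so species IVs sum to
300 over the community. A family's IV is the sum of its member species'
IVs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import CensusTable


def basal_area(dbh_cm) -> np.ndarray:
    """Stem cross-sectional area pi*(DBH/2)^2 in cm^2."""
    d = np.asarray(dbh_cm, dtype=float)
    return np.pi * (d / 2.0) ** 2


@dataclass
class ImportanceValueTable:
    """Per-species RF/RD/RA/IV (percent) and per-family IV."""

    species: pd.DataFrame
    family: pd.DataFrame


def importance_values(census: CensusTable) -> ImportanceValueTable:
    """IV = relative frequency + relative dominance + relative density.

    Frequency is counted over the plot's subplot grid (a species'
    frequency is the number of subplots it occupies); dominance is basal
    area; density is stem count. Each relative term sums to 100 over
    species, so IVs sum to 300.
    """
    if len(census) == 0:
        raise ValueError("empty census")
    df = census.data.copy()
    df["subplot"] = census.subplot_of_stems()
    df["ba"] = basal_area(df["dbh"])

    freq = df.groupby("species")["subplot"].nunique()
    dom = df.groupby("species")["ba"].sum()
    dens = df.groupby("species").size()

    out = pd.DataFrame(
        {
            "RF": 100.0 * freq / freq.sum(),
            "RD": 100.0 * dom / dom.sum(),
            "RA": 100.0 * dens / dens.sum(),
        }
    )
    out["IV"] = out["RF"] + out["RD"] + out["RA"]
    out = out.sort_values("IV", ascending=False)

    fam_of = census.taxonomy()["family"]
    fam = (
        out.join(fam_of)
        .groupby("family")[["RF", "RD", "RA", "IV"]]
        .sum()
        .sort_values("IV", ascending=False)
    )
    return ImportanceValueTable(out, fam)


def rank_abundance(census: CensusTable) -> pd.DataFrame:
    """Species-sequence curve data: abundance by rank, ties broken by
    species code (lexicographic)."""
    if len(census) == 0:
        raise ValueError("empty census")
    ab = census.abundances().reset_index()
    ab.columns = ["species", "abundance"]
    ab = ab.sort_values(
        ["abundance", "species"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    ab.insert(0, "rank", np.arange(1, len(ab) + 1))
    ab["log_rank"] = np.log(ab["rank"].astype(float))
    return ab


def fit_lognormal_sad(abundances, log: bool = True) -> tuple[float, float]:
    """Maximum-likelihood normal fit of the species-abundance distribution.

    With ``log=True`` (default) the fit is on natural-log abundances, i.e.
    a log-normal SAD — the standard reading of a humped species-sequence
    curve. ``log=False`` fits a plain normal to the raw abundances.

    Returns (mu, sigma); sigma is the MLE (ddof=0) estimate.
    """
    a = np.asarray(abundances, dtype=float)
    if a.size < 3:
        raise ValueError("need at least 3 species to fit an abundance distribution")
    if log:
        if np.any(a < 1):
            raise ValueError("abundances must be >= 1 for the log-normal fit")
        a = np.log(a)
    return float(np.mean(a)), float(np.std(a))


@dataclass
class AccumulationCurve:
    """Mean (and sd) distinct-taxon count vs number of accumulated
    subplots, over random subplot orderings."""

    level: str
    n_subplots: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_orderings: int


def accumulation_curve(
    census: CensusTable, level: str = "species", n_orderings: int = 200,
    seed: int | None = None,
) -> AccumulationCurve:
    """Taxon-area curve by random accumulation of the subplot grid.

    The curve at step k is the number of distinct taxa (species, genus or
    family) in the first k subplots of a random permutation, averaged over
    ``n_orderings`` permutations. Its endpoint is exactly the plot's taxon
    count; the mean curve is non-decreasing.
    """
    if level not in ("species", "genus", "family"):
        raise ValueError(f"unknown level {level!r}")
    if len(census) == 0:
        raise ValueError("empty census")
    rng = np.random.default_rng(seed)
    codes, taxa = pd.factorize(census.data[level])
    sub = np.asarray(census.subplot_of_stems())
    n_sub = census.window.n_subplots
    n_taxa = len(taxa)

    # per-subplot taxon incidence matrix (n_sub x n_taxa, boolean)
    inc = np.zeros((n_sub, n_taxa), dtype=bool)
    inc[sub, codes] = True

    curves = np.empty((n_orderings, n_sub), dtype=int)
    for i in range(n_orderings):
        order = rng.permutation(n_sub)
        seen = np.cumsum(inc[order], axis=0) > 0
        curves[i] = seen.sum(axis=1)
    return AccumulationCurve(
        level=level,
        n_subplots=np.arange(1, n_sub + 1),
        mean=curves.mean(axis=0),
        sd=curves.std(axis=0),
        n_orderings=n_orderings,
    )
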