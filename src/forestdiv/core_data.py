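"""Census-table I/O, validation, and composition classification.

A census is a stem map of one rectangular plot: one row per tree with a
unique tag, taxonomy (species/genus/family codes), plot-relative metric
coordinates, and diameter at breast height (DBH, cm). The census floor is
DBH >= 3 cm, the standard minimum for forest dynamics plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

CENSUS_COLUMNS = ["tag", "species", "genus", "family", "x", "y", "dbh"]

#: Census minimum DBH in cm (inclusive).
MIN_DBH = 3.0


class CensusValidationError(ValueError):
    """Raised when a census table violates its invariants."""


@dataclass(frozen=True)
class PlotWindow:
    """Rectangular observation window, gridded into square subplots.

    Parameters
    ----------
    width, height : float
        Plot extent in metres; must be positive multiples of
        ``subplot_size``.
    subplot_size : float
        Side of the square subplot grid cell (default 10 m, the
        conventional quadrat for 1-ha plots).
    """

    width: float = 100.0
    height: float = 100.0
    subplot_size: float = 10.0

    def __post_init__(self) -> None:
        for name in ("width", "height"):
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
            if not np.isclose(round(v / self.subplot_size) * self.subplot_size, v):
                raise ValueError(
                    f"{name}={v} is not a multiple of subplot_size={self.subplot_size}"
                )

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def n_subplots_x(self) -> int:
        return int(round(self.width / self.subplot_size))

    @property
    def n_subplots_y(self) -> int:
        return int(round(self.height / self.subplot_size))

    @property
    def n_subplots(self) -> int:
        return self.n_subplots_x * self.n_subplots_y

    def subplot_index(self, x, y):
        """Map coordinates to flat subplot indices (row-major from SW corner).

        Points on the far boundary are assigned to the last cell.
        """
        ix = np.minimum(
            (np.asarray(x) / self.subplot_size).astype(int), self.n_subplots_x - 1
        )
        iy = np.minimum(
            (np.asarray(y) / self.subplot_size).astype(int), self.n_subplots_y - 1
        )
        return iy * self.n_subplots_x + ix

    def contains(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= 0) & (x <= self.width) & (y >= 0) & (y <= self.height)


@dataclass
class CensusTable:
    """Validated stem-mapped census of one plot.

    ``data`` has columns tag, species, genus, family, x, y, dbh; row order
    is the file/generation order. Tags are unique; every species code maps
    to exactly one genus and family; all stems lie inside ``window`` and
    have DBH >= 3 cm.
    """

    data: pd.DataFrame
    window: PlotWindow = field(default_factory=PlotWindow)

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        validate_census(self.data, self.window)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_species(self) -> int:
        return self.data["species"].nunique()

    def abundances(self) -> pd.Series:
        """Stems per species, indexed by species code."""
        return self.data["species"].value_counts().sort_index()

    def species_points(self, species: str) -> np.ndarray:
        sub = self.data[self.data["species"] == species]
        if sub.empty:
            raise KeyError(f"species {species!r} not in census")
        return sub[["x", "y"]].to_numpy(float)

    def taxonomy(self) -> pd.DataFrame:
        """Unique species -> genus/family mapping."""
        return (
            self.data[["species", "genus", "family"]]
            .drop_duplicates("species")
            .set_index("species")
        )

    def subplot_of_stems(self) -> np.ndarray:
        return self.window.subplot_index(self.data["x"], self.data["y"])


def validate_census(df: pd.DataFrame, window: PlotWindow, min_dbh: float = MIN_DBH) -> None:
    missing = [c for c in CENSUS_COLUMNS if c not in df.columns]
    if missing:
        raise CensusValidationError(f"missing columns: {missing}")
    if df.empty:
        return
    dup = df["tag"][df["tag"].duplicated()]
    if not dup.empty:
        i = dup.index[0]
        raise CensusValidationError(f"duplicate tag {df['tag'][i]!r} at row {i}")
    for col in ("species", "genus", "family"):
        bad = df.index[df[col].astype(str).str.len() == 0]
        if len(bad):
            raise CensusValidationError(f"empty {col} at row {bad[0]}")
    inside = window.contains(df["x"], df["y"])
    if not inside.all():
        i = int(np.flatnonzero(~inside)[0])
        raise CensusValidationError(
            f"coordinate ({df['x'][i]}, {df['y'][i]}) outside "
            f"{window.width}x{window.height} m window at row {i}"
        )
    small = df.index[df["dbh"] < min_dbh]
    if len(small):
        i = small[0]
        raise CensusValidationError(
            f"dbh {df['dbh'][i]} below census minimum {min_dbh} cm at row {i}"
        )
    tax = df.groupby("species")[["genus", "family"]].nunique()
    bad = tax[(tax > 1).any(axis=1)]
    if not bad.empty:
        raise CensusValidationError(
            f"species {bad.index[0]!r} maps to multiple genera/families"
        )


def read_census(path, window: PlotWindow | None = None) -> CensusTable:
    """Read a census CSV (header tag,species,genus,family,x,y,dbh).

    Invalid rows are rejected with the offending row index in the message.
    """
    df = pd.read_csv(
        path,
        dtype={"tag": str, "species": str, "genus": str, "family": str},
        keep_default_na=False,
    )
    if not df.empty:
        df["x"] = df["x"].astype(float)
        df["y"] = df["y"].astype(float)
        df["dbh"] = df["dbh"].astype(float)
    else:
        df = df.reindex(columns=CENSUS_COLUMNS)
        df = df.astype({"x": float, "y": float, "dbh": float, "tag": str,
                        "species": str, "genus": str, "family": str})
    return CensusTable(df[CENSUS_COLUMNS] if set(CENSUS_COLUMNS) <= set(df.columns) else df,
                       window or PlotWindow())


def write_census(census: CensusTable, path) -> None:
    census.data.to_csv(path, index=False)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, as used for printed percentage tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int, ndigits: int = 2) -> float:
    """count/total as a percentage, half-up rounded to printed precision."""
    if total == 0:
        raise ValueError("total is zero")
    return round_half_up(100.0 * count / total, ndigits)


@dataclass
class ClassificationSummary:
    """Per-class unit (species or family) and stem counts with shares.

    ``table`` rows are classes; columns: n_units, unit_pct, n_stems,
    stem_pct. ``labels`` maps each unit to its class.
    """

    table: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        t = self.table
        assert int(t["n_units"].sum()) == len(self.labels)
        for cnt, pct in (("n_units", "unit_pct"), ("n_stems", "stem_pct")):
            total = int(t[cnt].sum())
            expect = [percentage(c, total) for c in t[cnt]]
            assert list(t[pct]) == expect, "percentages must recompute from counts"


def _classification(units_stems: pd.DataFrame, bounds: dict[str, tuple[float, float]],
                    key: pd.Series) -> ClassificationSummary:
    labels = pd.Series(index=key.index, dtype=object)
    for cls, (lo, hi) in bounds.items():
        labels[(key >= lo) & (key <= hi)] = cls
    rows = []
    total_units = len(units_stems)
    total_stems = int(units_stems["n_stems"].sum())
    for cls in bounds:
        sel = labels == cls
        n_u = int(sel.sum())
        n_s = int(units_stems.loc[sel, "n_stems"].sum())
        rows.append(
            {
                "class": cls,
                "n_units": n_u,
                "unit_pct": percentage(n_u, total_units),
                "n_stems": n_s,
                "stem_pct": percentage(n_s, total_stems),
            }
        )
    return ClassificationSummary(pd.DataFrame(rows).set_index("class"), labels)


def classify_species(census: CensusTable, dominant_min: int = 50) -> ClassificationSummary:
    """Partition species into dominant / common / rare abundance classes.

    Rare species have exactly one stem; dominant species have at least
    ``dominant_min`` stems (default 50, the printed table convention);
    everything in between is common.
    """
    if len(census) == 0:
        raise ValueError("empty census")
    ab = census.abundances()
    stems = ab.to_frame("n_stems")
    bounds = {
        "dominant": (dominant_min, np.inf),
        "common": (2, dominant_min - 1),
        "rare": (1, 1),
    }
    return _classification(stems, bounds, ab)


def classify_families(census: CensusTable, dominant_min: int = 5) -> ClassificationSummary:
    """Partition families by species richness: dominant (>=5 species),
    common (2-4), single (1)."""
    if len(census) == 0:
        raise ValueError("empty census")
    tax = census.taxonomy()
    sp_per_family = tax.groupby("family").size()
    stems_per_family = census.data.groupby("family").size()
    stems = pd.DataFrame(
        {"n_stems": stems_per_family.reindex(sp_per_family.index, fill_value=0)}
    )
    bounds = {
        "dominant": (dominant_min, np.inf),
        "common": (2, dominant_min - 1),
        "single": (1, 1),
    }
    return _classification(stems, bounds, sp_per_family)


def pair_count(n: int) -> int:
    """Number of unordered pairs among n items, n(n-1)/2."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return n * (n - 1) // 2


def dbh_class_table(
    census: CensusTable, thresholds: tuple[float, ...] = (5, 10, 20, 30, 40, 50)
) -> pd.DataFrame:
    """Families/genera/species/stem counts among stems with DBH >= t.

    One row per threshold; every count is non-increasing in t because the
    filters are nested.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    rows = []
    for t in thresholds:
        sub = census.data[census.data["dbh"] >= t]
        rows.append(
            {
                "dbh_min": t,
                "n_families": sub["family"].nunique(),
                "n_genera": sub["genus"].nunique(),
                "n_species": sub["species"].nunique(),
                "n_stems": len(sub),
            }
        )
    return pd.DataFrame(rows).set_index("dbh_min")


def dbh_histogram(census: CensusTable, species: str, bin_width: float = 2.0) -> pd.DataFrame:
    """Diameter-class counts for one species in half-open [lo, lo+w) bins.

    Bins start at the census minimum (3 cm); counts sum to the species'
    abundance.
    """
    sub = census.data[census.data["species"] == species]
    if sub.empty:
        raise KeyError(f"species {species!r} not in census")
    d = sub["dbh"].to_numpy(float)
    lo = MIN_DBH
    n_bins = int(np.floor((d.max() - lo) / bin_width)) + 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(d, bins=edges)
    return pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts})
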