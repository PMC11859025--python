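"""Synthetic stem-mapped forest plots with known ground truth.

Generates two-plot style censuses whose every structural feature is
controlled: a log-normal species-abundance distribution with a long
rare-species tail, per-species spatial models (homogeneous Poisson, Thomas
cluster process, or Thomas + conspecific negative-density-dependent
thinning), inverse-J (shifted-exponential) DBH distributions with an
optional normally-distributed canopy species, a random genus/family
taxonomy, and a subplot environment table whose variables are linear in
subplot richness with stated coefficients. Ground-truth labels let
downstream envelope calls be scored as a classifier.

Defaults emulate a 1-ha tropical plot: 100 m x 100 m window, ~150 species,
~1,800 stems, roughly a third of species singletons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .core_data import CensusTable, PlotWindow
from .pointpattern import PointPattern

#: Environment model per variable: (intercept, slope per richness, noise sd).
DEFAULT_ENV_EFFECTS = {
    "pH": (4.8, 0.03, 0.15),
    "SOM": (8.0, -0.25, 1.2),
    "WC": (35.0, -0.5, 2.5),
    "TN": (2.2, -0.05, 0.25),
    "TP": (0.5, -0.01, 0.05),
    "TK": (9.0, -0.2, 1.0),
}


@dataclass
class SyntheticDesign:
    """Full parameterization of one simulated plot.

    SAD: abundance_s = max(1, round(LogNormal(sad_mu, sad_sigma))). The
    defaults (mu=1.2, sigma=1.6) give ~31% singleton species and ~1,800
    expected stems at S=150, the realistic 1-ha tropical census scale.

    Spatial models are assigned per species: a fraction ``p_thomas`` are
    Thomas-clustered (dispersal sd ``thomas_sigma`` m, mean ``thomas_mu``
    offspring per parent), a fraction ``p_ndd`` are Thomas-clustered then
    thinned by conspecific negative density dependence (each recruit
    survives with probability (1-ndd_delta)^m, m = conspecific parents
    within ndd_rho m), the rest are Poisson (CSR).

    ``habitat_segregation`` in [0, 1] adds habitat filtering: the plot
    carries a smooth binary habitat field (half the subplots each type),
    every clustered species prefers one type, and a candidate parent in
    the wrong habitat is rejected with this probability. It induces
    interspecific spatial segregation (negative associations) and lowers
    subplot niche overlap between species of opposite preference, the
    spatial signature of niche differentiation; 0 (default) keeps the
    pure point-process models.

    DBH: shifted exponential, min 3 cm, mean ``dbh_mean`` (inverse-J); if
    ``normal_dbh_species`` is true the most abundant species instead draws
    from Normal(18, 6) truncated at 3 cm (a canopy-conifer-like class
    structure).
    """

    width: float = 100.0
    height: float = 100.0
    subplot_size: float = 10.0
    n_species: int = 150
    sad_mu: float = 1.2
    sad_sigma: float = 1.6
    p_thomas: float = 0.25
    p_ndd: float = 0.15
    thomas_sigma: float = 3.0
    thomas_mu: float = 10.0
    ndd_delta: float = 0.6
    ndd_rho: float = 5.0
    habitat_segregation: float = 0.0
    dbh_mean: float = 6.0
    normal_dbh_species: bool = True
    mean_genera_per_family: float = 2.2
    mean_species_per_genus: float = 1.8
    env_effects: dict = field(default_factory=lambda: dict(DEFAULT_ENV_EFFECTS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if not 0 <= self.p_thomas + self.p_ndd <= 1:
            raise ValueError("spatial-model fractions must lie in [0, 1]")
        for name in ("sad_sigma", "thomas_sigma", "thomas_mu", "ndd_rho", "dbh_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.ndd_delta <= 1:
            raise ValueError("ndd_delta must be in [0, 1]")
        if not 0 <= self.habitat_segregation <= 1:
            raise ValueError("habitat_segregation must be in [0, 1]")
        # normalize YAML lists so designs round-trip through to_yaml/from_yaml
        self.env_effects = {k: tuple(v) for k, v in self.env_effects.items()}

    @property
    def window(self) -> PlotWindow:
        return PlotWindow(self.width, self.height, self.subplot_size)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticDesign":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def lowland_like_design(seed: int = 0, **overrides) -> SyntheticDesign:
    """A species-rich plot dominated by clustered, NDD-thinned recruitment
    with strong habitat filtering (dispersal limitation + Janzen-Connell
    pressure + niche differentiation)."""
    kw = dict(n_species=150, p_thomas=0.45, p_ndd=0.25,
              habitat_segregation=0.95, seed=seed)
    kw.update(overrides)
    return SyntheticDesign(**kw)


def montane_like_design(seed: int = 0, **overrides) -> SyntheticDesign:
    """A less rich plot where most species are near-randomly placed and
    habitat filtering is weak (broad, overlapping niches)."""
    kw = dict(n_species=120, p_thomas=0.12, p_ndd=0.05,
              habitat_segregation=0.25, seed=seed)
    kw.update(overrides)
    return SyntheticDesign(**kw)


def sample_abundances(S: int, mu: float, sigma: float, seed=None) -> np.ndarray:
    """Species abundances max(1, round(LogNormal(mu, sigma))), giving a
    long singleton tail when sigma is large relative to mu."""
    if S < 1:
        raise ValueError("S must be >= 1")
    rng = np.random.default_rng(seed)
    a = np.rint(rng.lognormal(mu, sigma, size=S)).astype(int)
    return np.maximum(a, 1)


def simulate_thomas(
    kappa: float, sigma_c: float, mu_c: float, window: PlotWindow, seed=None,
) -> PointPattern:
    """Modified Thomas cluster process on the window.

    Poisson(kappa * area) parents uniform on the window; Poisson(mu_c)
    offspring per parent, displaced by isotropic Gaussian(sigma_c) noise
    and wrapped toroidally, which keeps the intensity uniform so the
    closed-form pcf 1 + exp(-r^2/4sigma^2)/(4 pi sigma^2 kappa) applies.
    Only offspring are returned (intensity kappa * mu_c).
    """
    if min(kappa, sigma_c, mu_c) <= 0:
        raise ValueError("Thomas parameters must be positive")
    rng = np.random.default_rng(seed)
    n_parents = rng.poisson(kappa * window.area)
    parents = rng.random((n_parents, 2)) * np.array([window.width, window.height])
    n_off = rng.poisson(mu_c, size=n_parents)
    pts = np.repeat(parents, n_off, axis=0) + rng.normal(
        0.0, sigma_c, size=(int(n_off.sum()), 2)
    )
    pts[:, 0] %= window.width
    pts[:, 1] %= window.height
    return PointPattern(pts, window)


def make_habitat_field(window: PlotWindow, seed=None) -> np.ndarray:
    """Smooth binary habitat map over the subplot grid (flat-indexed).

    Gaussian noise on the grid, 5x5 neighbour-averaged (toroidal), then
    thresholded at its median so each habitat covers half the subplots;
    the averaging yields patches a few subplots wide, the scale of real
    topographic habitat mosaics in 1-ha plots.
    """
    from scipy.ndimage import uniform_filter

    rng = np.random.default_rng(seed)
    z = rng.normal(size=(window.n_subplots_y, window.n_subplots_x))
    z = uniform_filter(z, size=5, mode="wrap")
    return (z > np.median(z)).ravel()


def _habitat_parents(n_parents: int, window: PlotWindow, habitat: np.ndarray,
                     preferred: bool, segregation: float, rng) -> np.ndarray:
    """Uniform parents filtered toward one habitat type by rejection:
    a candidate in the wrong habitat survives with prob 1 - segregation."""
    out = np.empty((0, 2))
    while len(out) < n_parents:
        cand = rng.random((4 * n_parents, 2)) * np.array([window.width, window.height])
        wrong = habitat[window.subplot_index(cand[:, 0], cand[:, 1])] != preferred
        keep = ~wrong | (rng.random(len(cand)) >= segregation)
        out = np.vstack([out, cand[keep]])
    return out[:n_parents]


def _thomas_offspring(n: int, sigma_c: float, mu_c: float, window: PlotWindow,
                      rng, habitat=None, preferred=True, segregation=0.0):
    """Exactly n offspring spread over ~n/mu_c parents (a count-conditioned
    Thomas draw used by the census generator), optionally habitat-filtered."""
    n_parents = max(1, int(round(n / mu_c)))
    if habitat is not None and segregation > 0:
        parents = _habitat_parents(n_parents, window, habitat, preferred,
                                   segregation, rng)
    else:
        parents = rng.random((n_parents, 2)) * np.array([window.width, window.height])
    assign = rng.integers(0, n_parents, size=n)
    pts = parents[assign] + rng.normal(0.0, sigma_c, size=(n, 2))
    pts[:, 0] %= window.width
    pts[:, 1] %= window.height
    return pts, parents


def apply_ndd_thinning(
    offspring: PointPattern, parents: np.ndarray, delta: float, rho: float, seed=None,
) -> PointPattern:
    """Conspecific distance-dependent thinning (Janzen-Connell style).

    Each offspring survives independently with probability (1-delta)^m,
    where m is the number of conspecific parent points within rho metres —
    recruits under many adults die most often.
    """
    if not 0 <= delta <= 1:
        raise ValueError("delta must be in [0, 1]")
    if rho <= 0:
        raise ValueError("rho must be positive")
    rng = np.random.default_rng(seed)
    pts = offspring.points
    parents = np.asarray(parents, dtype=float).reshape(-1, 2)
    if len(pts) == 0 or len(parents) == 0 or delta == 0:
        return PointPattern(pts.copy(), offspring.window)
    d = np.hypot(
        pts[:, 0][:, None] - parents[None, :, 0],
        pts[:, 1][:, None] - parents[None, :, 1],
    )
    m = (d <= rho).sum(axis=1)
    survive = rng.random(len(pts)) < (1.0 - delta) ** m
    return PointPattern(pts[survive], offspring.window)


def _make_taxonomy(S: int, mean_genera_per_family: float,
                   mean_species_per_genus: float, rng) -> pd.DataFrame:
    """Random species -> genus -> family assignment with 1+Poisson sizes,
    yielding a realistic mix of dominant, common and singleton families."""
    rows, g_id, f_id = [], 0, 0
    while len(rows) < S:
        f_id += 1
        n_gen = 1 + rng.poisson(mean_genera_per_family - 1.0)
        for _ in range(n_gen):
            g_id += 1
            n_sp = 1 + rng.poisson(mean_species_per_genus - 1.0)
            for _ in range(n_sp):
                rows.append((f"G{g_id:03d}", f"F{f_id:03d}"))
    rng.shuffle(rows)
    rows = rows[:S]
    return pd.DataFrame(
        {
            "species": [f"SP{i + 1:03d}" for i in range(S)],
            "genus": [r[0] for r in rows],
            "family": [r[1] for r in rows],
        }
    )


def _sample_dbh(n: int, kind: str, dbh_mean: float, rng) -> np.ndarray:
    if kind == "normal":
        d = rng.normal(18.0, 6.0, size=n)
        while (bad := d < 3.0).any():  # truncate at the census floor
            d[bad] = rng.normal(18.0, 6.0, size=int(bad.sum()))
        return d
    return 3.0 + rng.exponential(dbh_mean - 3.0, size=n)


def generate_census(design: SyntheticDesign):
    """Draw one full plot: (CensusTable, env table, ground-truth table).

    The ground-truth table records each species' spatial class
    (poisson / thomas / ndd), its realized abundance, and its DBH model.
    Environment variables are linear in realized subplot richness with the
    design's stated coefficients plus Gaussian noise, so richness-
    environment slopes are recoverable by OLS. Reproducible from
    ``design.seed``; the census round-trips through the package's CSV I/O.
    """
    root = np.random.SeedSequence(design.seed)
    rng_ab, rng_tax, rng_spatial, rng_dbh, rng_env = (
        np.random.default_rng(s) for s in root.spawn(5)
    )
    window = design.window
    S = design.n_species
    abundances = sample_abundances(S, design.sad_mu, design.sad_sigma, rng_ab)
    taxonomy = _make_taxonomy(
        S, design.mean_genera_per_family, design.mean_species_per_genus, rng_tax
    )

    kinds = np.array(["poisson"] * S, dtype=object)
    u = rng_spatial.random(S)
    kinds[u < design.p_thomas] = "thomas"
    kinds[(u >= design.p_thomas) & (u < design.p_thomas + design.p_ndd)] = "ndd"

    dbh_kinds = np.array(["exponential"] * S, dtype=object)
    if design.normal_dbh_species:
        dbh_kinds[int(np.argmax(abundances))] = "normal"

    habitat = make_habitat_field(window, rng_spatial)
    # balanced habitat preferences: half the species favour each type
    preference = rng_spatial.permutation(np.arange(S) % 2).astype(bool)

    frames, truth_rows = [], []
    for s in range(S):
        n_s = int(abundances[s])
        if kinds[s] == "poisson" or n_s < 2:
            pts = rng_spatial.random((n_s, 2)) * np.array([window.width, window.height])
            realized_kind = "poisson" if kinds[s] == "poisson" else kinds[s]
        else:
            pts, parents = _thomas_offspring(
                n_s, design.thomas_sigma, design.thomas_mu, window, rng_spatial,
                habitat=habitat, preferred=bool(preference[s]),
                segregation=design.habitat_segregation,
            )
            realized_kind = kinds[s]
            if kinds[s] == "ndd":
                thinned = apply_ndd_thinning(
                    PointPattern(pts, window), parents,
                    design.ndd_delta, design.ndd_rho, rng_spatial,
                )
                # keep at least one stem so the species stays in the census
                pts = thinned.points if thinned.n >= 1 else pts[:1]
        n_real = len(pts)
        dbh = _sample_dbh(n_real, dbh_kinds[s], design.dbh_mean, rng_dbh)
        frames.append(
            pd.DataFrame(
                {
                    "species": taxonomy["species"][s],
                    "genus": taxonomy["genus"][s],
                    "family": taxonomy["family"][s],
                    "x": pts[:, 0],
                    "y": pts[:, 1],
                    "dbh": np.round(dbh, 2),
                }
            )
        )
        truth_rows.append(
            {
                "species": taxonomy["species"][s],
                "spatial_class": realized_kind,
                "abundance": n_real,
                "dbh_model": dbh_kinds[s],
            }
        )

    data = pd.concat(frames, ignore_index=True)
    data.insert(0, "tag", [f"T{i + 1:05d}" for i in range(len(data))])
    data[["x", "y"]] = data[["x", "y"]].round(3)
    census = CensusTable(data, window)
    truth = pd.DataFrame(truth_rows)

    from .env_stats import subplot_richness

    rich = subplot_richness(census)
    env = pd.DataFrame({"subplot": rich.index})
    for var, (a, b, sd) in design.env_effects.items():
        env[var] = np.round(
            a + b * rich.to_numpy() + rng_env.normal(0.0, sd, size=len(rich)), 4
        )
    return census, env, truth
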