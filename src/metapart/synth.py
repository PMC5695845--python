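"""Synthetic landscapes, metacommunities and tree censuses with known structure.

Because no field data accompany the analysis, every pipeline stage is
exercised on generated data whose generating process is known.  The
generator mirrors the field design this pipeline targets: 46 plots of
25 × 100 m, a pool of 230 tree species with few common and many rare species
(log-series-like base abundances), five spatially autocorrelated topographic
covariates, and community structure under four metacommunity archetypes:

* ``species_sorting`` — species respond to the environment through Gaussian
  niches on a covariate gradient;
* ``neutral`` — no environmental response; each species carries its own
  spatially autocorrelated latent intensity field (phenomenological
  dispersal limitation);
* ``mass_effect`` — a mixture of the two (weight ``mixture_w`` on the
  environmental term);
* ``null`` — neither environmental nor spatial structure.

Counts are Poisson (negative binomial when ``noise`` > 0) around the
archetype's intensity surface.  All generators are pure functions of their
configuration and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .census import CommunityMatrix, TreeRecord
from .spatial import distance_matrix

__all__ = [
    "ScenarioConfig",
    "ENV_FIELD_NAMES",
    "gen_coords",
    "gen_env_fields",
    "gen_metacommunity",
    "metacommunity_intensity",
    "gen_tree_census",
    "generate_scenario",
]

ARCHETYPES = ("species_sorting", "mass_effect", "neutral", "null")

#: synthetic stand-ins for the five per-plot topographic covariates
ENV_FIELD_NAMES = ("elevation", "slope", "profile_curv", "plan_curv", "hand")


@dataclass
class ScenarioConfig:
    """Generating parameters of one synthetic metacommunity.

    Defaults mirror the field design (46 plots, 230 species) with covariate
    and dispersal autocorrelation ranges of 500 m across a 2 km extent, a
    log-series-like rank-abundance shape θ = 0.995 and ~130 stems per plot.
    """

    archetype: str
    seed: int
    n_plots: int = 46
    n_species: int = 230
    extent: float = 2000.0
    coord_mode: str = "uniform_random"
    env_range: float = 500.0
    sill: float = 1.0
    niche_sd: float = 0.7
    mixture_w: float = 0.5
    spatial_range: float = 500.0
    abundance_rank_shape: float = 0.995
    noise: float = 0.0
    mean_stems_per_plot: float = 130.0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}; one of {ARCHETYPES}")
        if not 0.0 <= self.mixture_w <= 1.0:
            raise ValueError("mixture_w must be in [0, 1]")
        if self.n_plots < 4:
            raise ValueError("n_plots must be >= 4")
        for name in ("extent", "env_range", "spatial_range", "sill"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    def rng_for(self, stage: str) -> np.random.Generator:
        """Independent reproducible stream per stage, keyed by stage name."""
        import zlib

        return np.random.default_rng(
            np.random.SeedSequence([self.seed % 2**31, zlib.crc32(stage.encode()) % 2**31])
        )

    def to_dict(self) -> dict:
        return asdict(self)


def gen_coords(
    n_plots: int,
    extent: float,
    mode: str = "uniform_random",
    seed: int = 0,
) -> np.ndarray:
    """Plot coordinates (m): i.i.d. uniform, regular grid, or 1-D transect."""
    if not extent > 0:
        raise ValueError("extent must be > 0")
    rng = np.random.default_rng(seed)
    if mode == "uniform_random":
        return rng.uniform(0.0, extent, size=(n_plots, 2))
    if mode == "transect":
        x = np.linspace(0.0, extent, n_plots)
        return np.column_stack([x, np.zeros(n_plots)])
    if mode == "grid":
        rows = int(round(np.sqrt(n_plots)))
        cols = int(np.ceil(n_plots / rows))
        if rows * cols != n_plots:
            warnings.warn(
                f"{n_plots} plots do not fill a square grid; using {rows}×{cols} "
                f"and keeping the first {n_plots} nodes"
            )
        xs = np.linspace(0.0, extent, cols)
        ys = np.linspace(0.0, extent, rows)
        pts = np.array([(x, y) for y in ys for x in xs])
        return pts[:n_plots]
    raise ValueError(f"unknown coordinate mode {mode!r}")


def _gp_factor(coords: np.ndarray, range_: float, sill: float) -> np.ndarray:
    """Cholesky factor of the exponential covariance sill·exp(−d/range)."""
    d = distance_matrix(coords)
    cov = sill * np.exp(-d / range_)
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        warnings.warn("covariance numerically non-PD; jittering the diagonal")
        return np.linalg.cholesky(cov + 1e-10 * np.eye(len(cov)))


def gen_env_fields(
    coords: np.ndarray,
    n_fields: int = 5,
    range_: float = 500.0,
    sill: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Spatially autocorrelated covariate fields (zero-mean GP draws).

    Each field is an independent draw from a Gaussian process with
    exponential covariance sill·exp(−d/range); with five fields the columns
    carry the topographic covariate names they stand in for.
    """
    if not range_ > 0 or not sill > 0:
        raise ValueError("range and sill must be > 0")
    rng = np.random.default_rng(seed)
    chol = _gp_factor(coords, range_, sill)
    fields = chol @ rng.standard_normal((len(coords), n_fields))
    names = (
        list(ENV_FIELD_NAMES)
        if n_fields == len(ENV_FIELD_NAMES)
        else [f"env{j + 1}" for j in range(n_fields)]
    )
    return pd.DataFrame(fields, columns=names)


def _base_abundances(n_species: int, theta: float) -> np.ndarray:
    """Log-series-like base abundances A_s ∝ θ^s / s (few common, many rare)."""
    s = np.arange(1, n_species + 1)
    a = theta**s / s
    return a / a.sum()


def metacommunity_intensity(
    sc: ScenarioConfig, coords: np.ndarray, env: pd.DataFrame
) -> np.ndarray:
    """Expected counts (plots × species) under the scenario's archetype.

    Deterministic given the config (species optima and latent spatial fields
    are drawn from seed-derived streams independent of the count noise), so
    limits such as mixture_w → 1 or niche_sd → ∞ can be checked exactly.
    """
    n, s = sc.n_plots, sc.n_species
    base = _base_abundances(s, sc.abundance_rank_shape)
    log_lam = np.tile(np.log(base), (n, 1))

    needs_env = sc.archetype == "species_sorting" or (
        sc.archetype == "mass_effect" and sc.mixture_w > 0
    )
    env_term = np.zeros((n, s))
    if sc.archetype in ("species_sorting", "mass_effect"):
        if env is None:
            raise ValueError(f"{sc.archetype} requires environmental covariates")
        grad = env.to_numpy(dtype=float)[:, 0]  # niche axis: first covariate
        rng_opt = sc.rng_for("niche_optima")
        optima = rng_opt.uniform(grad.min(), grad.max(), size=s)
        env_term = -((grad[:, None] - optima[None, :]) ** 2) / (2.0 * sc.niche_sd**2)
    spa_term = np.zeros((n, s))
    if sc.archetype in ("neutral", "mass_effect"):
        rng_spa = sc.rng_for("latent_spatial_fields")
        chol = _gp_factor(coords, sc.spatial_range, sc.sill)
        spa_term = chol @ rng_spa.standard_normal((n, s))

    if sc.archetype == "species_sorting":
        log_lam += env_term
    elif sc.archetype == "neutral":
        log_lam += spa_term
    elif sc.archetype == "mass_effect":
        log_lam += sc.mixture_w * env_term + (1.0 - sc.mixture_w) * spa_term
    # null: base abundances only

    lam = np.exp(log_lam)
    target = sc.n_plots * sc.mean_stems_per_plot
    return lam * (target / lam.sum())


def gen_metacommunity(
    sc: ScenarioConfig, coords: np.ndarray, env: pd.DataFrame | None
) -> CommunityMatrix:
    """Draw an abundance community matrix around the archetype's intensities.

    Counts are Poisson; with ``noise`` > 0 they are negative binomial
    (gamma–Poisson mixture) with overdispersion var = μ + noise · μ².
    """
    lam = metacommunity_intensity(sc, coords, env)
    rng = sc.rng_for("counts")
    if sc.noise > 0:
        shape = 1.0 / sc.noise
        lam = rng.gamma(shape, lam / shape)
    counts = rng.poisson(lam)
    plot_ids = [f"P{i + 1:03d}" for i in range(sc.n_plots)]
    species_ids = [f"sp{j + 1:03d}" for j in range(sc.n_species)]
    df = pd.DataFrame(
        counts.astype(float), index=pd.Index(plot_ids, name="plot_id"), columns=species_ids
    )
    return CommunityMatrix(df, basis="abundance", unit="stems")


def gen_tree_census(
    m: CommunityMatrix,
    dbh_scale: float = 10.0,
    min_dbh: float = 10.0,
    height_alpha: float = 2.0,
    height_beta: float = 0.6,
    height_sigma: float = 0.1,
    seed: int = 0,
) -> list[TreeRecord]:
    """Expand an abundance matrix into per-stem records with sizes.

    DBH is min_dbh plus an exponential excess (mean ``dbh_scale`` cm); height
    follows the power law h = α·DBH^β with multiplicative lognormal noise —
    typical shapes for tropical stands censused at a 10 cm threshold.
    """
    if m.basis != "abundance":
        raise ValueError("tree census generation needs an abundance matrix")
    rng = np.random.default_rng(seed)
    records: list[TreeRecord] = []
    vals = m.values.astype(int)
    for i, plot in enumerate(m.plot_ids):
        for j, sp in enumerate(m.species_ids):
            k = vals[i, j]
            if k == 0:
                continue
            dbh = min_dbh + rng.exponential(dbh_scale, size=k)
            height = (
                height_alpha
                * dbh**height_beta
                * np.exp(rng.normal(0.0, height_sigma, size=k))
            )
            records.extend(
                TreeRecord(plot, sp, float(d), float(h)) for d, h in zip(dbh, height)
            )
    return records


def generate_scenario(sc: ScenarioConfig) -> dict:
    """One full synthetic dataset: coordinates, covariates, community, census.

    Returns a dict with keys ``coords`` (n × 2 array), ``plots`` (DataFrame in
    the plots.csv schema), ``community`` (abundance CommunityMatrix),
    ``trees`` (list of TreeRecord) and ``config``.
    """
    coords = gen_coords(
        sc.n_plots, sc.extent, sc.coord_mode, seed=sc.rng_for("coords").integers(2**31)
    )
    env = gen_env_fields(
        coords,
        n_fields=len(ENV_FIELD_NAMES),
        range_=sc.env_range,
        sill=sc.sill,
        seed=sc.rng_for("env_fields").integers(2**31),
    )
    community = gen_metacommunity(sc, coords, env)
    trees = gen_tree_census(
        community, seed=int(sc.rng_for("tree_census").integers(2**31))
    )
    plots = env.copy()
    plots.insert(0, "y_m", coords[:, 1])
    plots.insert(0, "x_m", coords[:, 0])
    plots.insert(0, "plot_id", community.plot_ids)
    return {
        "coords": coords,
        "plots": plots,
        "community": community,
        "trees": trees,
        "config": sc,
    }
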