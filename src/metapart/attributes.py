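"""Community response attributes: univariate vectors and composition matrices.

Six attributes are derived per species group (total community, common
species, information-equalized rare species):

* ``std_richness`` — residuals of the OLS regression of plot richness on plot
  abundance, i.e. richness freed of its abundance component;
* ``abundance`` / ``biomass`` — per-plot totals;
* ``c_incidence`` / ``c_abundance`` / ``c_biomass`` — composition matrices on
  each basis, with the abundance composition Hellinger-transformed by default
  (cell' = sqrt(cell / row total)), which makes Euclidean-based ordination
  appropriate for sparse community data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .census import CommunityMatrix, to_incidence
from .commonness import CommonRareSplit, subset_matrix

__all__ = [
    "AttributeVector",
    "ResponseMatrix",
    "plot_totals",
    "richness",
    "standardized_richness",
    "hellinger",
    "build_responses",
    "ATTRIBUTES",
    "GROUPS",
]

ATTRIBUTES = (
    "std_richness",
    "abundance",
    "biomass",
    "c_incidence",
    "c_abundance",
    "c_biomass",
)
GROUPS = ("total", "common", "rare")

#: attributes whose species groups come from the biomass-based ranking
BIOMASS_SPLIT_ATTRIBUTES = ("biomass", "c_biomass")


@dataclass
class AttributeVector:
    """Per-plot univariate attribute."""

    plot_ids: list[str]
    values: np.ndarray
    name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.plot_ids) != len(self.values):
            raise ValueError("plot_ids and values must have equal length")

    def as_column(self) -> np.ndarray:
        return self.values.reshape(-1, 1)


@dataclass
class ResponseMatrix:
    """Plots × species response matrix with its transform tag."""

    data: pd.DataFrame
    transform: str  # {none, hellinger}

    @property
    def plot_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def plot_totals(m: CommunityMatrix) -> AttributeVector:
    """Row sums: total abundance (or biomass) of each plot."""
    if m.basis not in ("abundance", "biomass"):
        raise ValueError("plot totals require an abundance or biomass matrix")
    name = "total_abundance" if m.basis == "abundance" else "total_biomass"
    return AttributeVector(m.plot_ids, m.values.sum(axis=1), name)


def richness(m: CommunityMatrix) -> AttributeVector:
    """Per-plot count of species with a positive cell."""
    return AttributeVector(m.plot_ids, (m.values > 0).sum(axis=1), "richness")


def standardized_richness(
    rich: AttributeVector, abund: AttributeVector
) -> AttributeVector:
    """Richness freed of abundance: OLS residuals of richness on abundance."""
    if rich.plot_ids != abund.plot_ids:
        raise ValueError("plot ids of richness and abundance must match")
    if len(rich.values) < 3:
        raise ValueError("need at least 3 plots")
    x = abund.values
    if np.ptp(x) == 0:
        raise ValueError("abundance is constant: regression slope undefined")
    slope, intercept = np.polyfit(x, rich.values, 1)
    resid = rich.values - (intercept + slope * x)
    return AttributeVector(rich.plot_ids, resid, "std_richness")


def hellinger(m: CommunityMatrix) -> ResponseMatrix:
    """Hellinger transform: cell' = sqrt(cell / row total).

    Rows with zero total stay all-zero (warned); every other transformed row
    has unit sum of squares.
    """
    vals = m.values
    if (vals < 0).any():
        raise ValueError("Hellinger transform requires nonnegative values")
    totals = vals.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} plot(s) with zero total kept as all-zero rows"
        )
    safe = np.where(totals > 0, totals, 1.0)
    out = np.sqrt(vals / safe)
    df = pd.DataFrame(out, index=m.data.index, columns=m.data.columns)
    return ResponseMatrix(df, transform="hellinger")


def _group_ids(m: CommunityMatrix, split: CommonRareSplit, group: str) -> list[str]:
    if group == "total":
        return m.species_ids
    if group == "common":
        return split.common_ids
    if group == "rare":
        return split.trimmed_rare_ids
    raise ValueError(f"unknown group {group!r}")


def build_responses(
    abundance_m: CommunityMatrix,
    biomass_m: CommunityMatrix,
    split_abundance: CommonRareSplit,
    split_biomass: CommonRareSplit,
    hellinger_biomass: bool = False,
) -> dict[tuple[str, str], AttributeVector | ResponseMatrix]:
    """All 18 response objects: 6 attributes × 3 species groups.

    The abundance-based split governs std_richness, abundance and the
    incidence/abundance compositions; the biomass-based split governs the
    biomass attributes.  The abundance composition is Hellinger-transformed;
    incidence stays raw 0/1; the biomass composition is raw unless
    ``hellinger_biomass`` is set.
    """
    out: dict[tuple[str, str], AttributeVector | ResponseMatrix] = {}
    for group in GROUPS:
        ab = subset_matrix(abundance_m, _group_ids(abundance_m, split_abundance, group))
        bm = subset_matrix(biomass_m, _group_ids(biomass_m, split_biomass, group))
        for attr, obj in _group_responses(ab, bm, hellinger_biomass).items():
            out[(attr, group)] = obj
    return out


def _group_responses(
    ab: CommunityMatrix, bm: CommunityMatrix, hellinger_biomass: bool
) -> dict[str, AttributeVector | ResponseMatrix]:
    if ab.n_species < 2 or bm.n_species < 2:
        raise ValueError("composition attributes need at least 2 species per group")
    abund_tot = plot_totals(ab)
    resp: dict[str, AttributeVector | ResponseMatrix] = {
        "std_richness": standardized_richness(richness(ab), abund_tot),
        "abundance": abund_tot,
        "biomass": plot_totals(bm),
        "c_incidence": ResponseMatrix(to_incidence(ab).data, transform="none"),
        "c_abundance": hellinger(ab),
        "c_biomass": (
            hellinger(bm)
            if hellinger_biomass
            else ResponseMatrix(bm.data.astype(float), transform="none")
        ),
    }
    return resp
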