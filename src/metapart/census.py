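"""Tree-census ingestion, stem filtering, allometric biomass and plot × species matrices.

The raw input is one row per censused stem (plot id, species id, DBH in cm,
total height in m).  Stems below the inclusion diameter are dropped, per-stem
aboveground biomass is computed from a DBH²·H power law, and stems are
aggregated into community matrices with plots as rows and species as columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TreeRecord",
    "AllometricModel",
    "CommunityMatrix",
    "filter_census",
    "tree_biomass",
    "build_matrix",
    "to_incidence",
    "read_trees_csv",
    "write_trees_csv",
    "read_matrix_csv",
    "write_matrix_csv",
    "survey_summary",
]

#: valid bases for a community matrix
BASES = ("incidence", "abundance", "biomass")

#: plot geometry of the field design this pipeline mirrors
PLOT_WIDTH_M = 25.0
PLOT_LENGTH_M = 100.0


@dataclass(frozen=True)
class TreeRecord:
    """One censused stem.

    Attributes
    ----------
    plot_id : str
        Plot the stem was recorded in.
    species_id : str
        Species identity (all stems must be identified).
    dbh : float
        Diameter at breast height, cm.
    height : float
        Total height, m.
    """

    plot_id: str
    species_id: str
    dbh: float
    height: float

    def __post_init__(self) -> None:
        if not str(self.plot_id).strip():
            raise ValueError("plot_id must be non-empty")
        if not str(self.species_id).strip():
            raise ValueError(
                "species_id must be non-empty: unidentified stems are rejected"
            )
        if not self.dbh > 0:
            raise ValueError(f"dbh must be > 0, got {self.dbh}")
        if not self.height > 0:
            raise ValueError(f"height must be > 0, got {self.height}")


@dataclass(frozen=True)
class AllometricModel:
    """Aboveground-biomass power law  B = coefficient · (DBH² · H)^exponent.

    DBH in cm, H in m; the output is treated as kilograms (the unit label is
    metadata only — no downstream computation depends on it).
    """

    coefficient: float = 0.044
    exponent: float = 0.9719
    unit: str = "kg"

    def __post_init__(self) -> None:
        if not self.coefficient > 0:
            raise ValueError("coefficient must be > 0")
        if not self.exponent > 0:
            raise ValueError("exponent must be > 0")


def tree_biomass(model: AllometricModel, dbh: float, height: float) -> float:
    """Per-stem aboveground biomass from the allometric power law.

    Parameters are the stem's DBH (cm) and total height (m); returns
    ``coefficient * (dbh**2 * height) ** exponent``.
    """
    if not dbh > 0 or not height > 0:
        raise ValueError(f"dbh and height must be > 0, got dbh={dbh}, height={height}")
    return model.coefficient * (dbh * dbh * height) ** model.exponent


def filter_census(
    records: Sequence[TreeRecord], min_dbh: float = 10.0
) -> list[TreeRecord]:
    """Keep stems with DBH >= ``min_dbh`` (boundary inclusive), order preserved."""
    if not min_dbh > 0:
        raise ValueError(f"min_dbh must be > 0, got {min_dbh}")
    return [r for r in records if r.dbh >= min_dbh]


@dataclass
class CommunityMatrix:
    """Plots × species matrix on a declared basis.

    ``data`` is a DataFrame with plot ids as the index and species ids as
    columns.  ``basis`` is one of ``incidence`` (0/1), ``abundance``
    (nonnegative integer stem counts) or ``biomass`` (nonnegative reals).
    """

    data: pd.DataFrame
    basis: str
    unit: str | None = None

    def __post_init__(self) -> None:
        if self.basis not in BASES:
            raise ValueError(f"basis must be one of {BASES}, got {self.basis!r}")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("plot and species id lists must be duplicate-free")
        vals = self.data.to_numpy(dtype=float)
        if (vals < 0).any():
            raise ValueError("community matrix values must be nonnegative")
        if self.basis == "incidence" and not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("incidence matrix must contain only 0 and 1")
        if self.basis == "abundance" and not np.allclose(vals, np.round(vals)):
            raise ValueError("abundance matrix must contain integers")

    @property
    def plot_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_plots(self) -> int:
        return self.data.shape[0]

    @property
    def n_species(self) -> int:
        return self.data.shape[1]


def build_matrix(
    records: Sequence[TreeRecord],
    basis: str,
    model: AllometricModel | None = None,
    plot_ids: Sequence[str] | None = None,
    species_ids: Sequence[str] | None = None,
) -> CommunityMatrix:
    """Aggregate (already filtered) stems into a plots × species matrix.

    ``abundance`` cells are stem counts; ``biomass`` cells are sums of per-stem
    allometric biomass.  Plot and species axes are sorted lexicographically;
    ids absent from the records appear only if supplied explicitly.
    """
    if basis not in ("abundance", "biomass"):
        raise ValueError(f"basis must be 'abundance' or 'biomass', got {basis!r}")
    if basis == "biomass" and model is None:
        model = AllometricModel()

    plots = sorted({r.plot_id for r in records} | set(plot_ids or ()))
    species = sorted({r.species_id for r in records} | set(species_ids or ()))
    arr = np.zeros((len(plots), len(species)))
    prow = {p: i for i, p in enumerate(plots)}
    scol = {s: j for j, s in enumerate(species)}
    for r in records:
        w = 1.0 if basis == "abundance" else tree_biomass(model, r.dbh, r.height)
        arr[prow[r.plot_id], scol[r.species_id]] += w
    df = pd.DataFrame(arr, index=pd.Index(plots, name="plot_id"), columns=species)
    unit = "stems" if basis == "abundance" else (model.unit if model else "kg")
    return CommunityMatrix(df, basis=basis, unit=unit)


def to_incidence(m: CommunityMatrix) -> CommunityMatrix:
    """Presence/absence version of an abundance or biomass matrix (idempotent)."""
    df = (m.data > 0).astype(float)
    return CommunityMatrix(df, basis="incidence")


# ---------------------------------------------------------------------------
# I/O

def read_trees_csv(path) -> list[TreeRecord]:
    """Read a stem table (columns plot_id, species_id, dbh_cm, height_m)."""
    df = pd.read_csv(path, dtype={"plot_id": str, "species_id": str})
    required = {"plot_id", "species_id", "dbh_cm", "height_m"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trees table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        pid, sid = str(row.plot_id), str(row.species_id)
        if not sid.strip() or sid.lower() == "nan":
            raise ValueError(
                f"unidentified stem in plot {pid!r}: blank species id is rejected"
            )
        records.append(
            TreeRecord(pid, sid, float(row.dbh_cm), float(row.height_m))
        )
    return records


def write_trees_csv(records: Iterable[TreeRecord], path) -> None:
    df = pd.DataFrame(
        [(r.plot_id, r.species_id, r.dbh, r.height) for r in records],
        columns=["plot_id", "species_id", "dbh_cm", "height_m"],
    )
    df.to_csv(path, index=False)


def read_matrix_csv(path, basis: str) -> CommunityMatrix:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return CommunityMatrix(df, basis=basis)


def write_matrix_csv(m: CommunityMatrix, path) -> None:
    m.data.to_csv(path, index_label="plot_id")


def survey_summary(
    plot_ids: Sequence[str],
    plot_width_m: float = PLOT_WIDTH_M,
    plot_length_m: float = PLOT_LENGTH_M,
) -> dict:
    """Plot-design metadata: count, per-plot area and total sampled area (ha)."""
    n = len(set(plot_ids))
    area_m2 = plot_width_m * plot_length_m
    return {
        "n_plots": n,
        "plot_area_m2": area_m2,
        "total_area_ha": n * area_m2 / 10_000.0,
    }
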