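"""End-to-end analysis: census → splits → responses → PCNM → selection → partition.

``run_analysis`` drives the whole chain and produces an 18-row report (six
community attributes × three species groups) in the style of a
variance-partitioning results table: adjusted-R² percentages for pure
topography, shared, pure space and unexplained components, with permutation
significance codes and the species-rank ranges of each group.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import census as census_mod
from .attributes import ATTRIBUTES, BIOMASS_SPLIT_ATTRIBUTES, GROUPS, build_responses
from .census import AllometricModel, CommunityMatrix
from .commonness import CommonRareSplit, split_common_rare
from .partition import VariancePartition, varpart
from .selection import SelectionResult, forward_select
from .spatial import (
    SpatialEigenbasis,
    distance_matrix,
    pcnm,
    screen_eigenbasis,
    validate_projected,
)

__all__ = [
    "AnalysisConfig",
    "AnalysisResult",
    "read_plots_csv",
    "run_analysis",
    "format_report",
    "stage_rng",
]

log = logging.getLogger(__name__)

PLOTS_COORD_COLS = ("x_m", "y_m")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent reproducible stream per pipeline stage, keyed by name.

    Forking per stage means adding permutations to one stage never perturbs
    the draws of another.
    """
    return np.random.default_rng(
        np.random.SeedSequence([seed % 2**31, zlib.crc32(stage.encode()) % 2**31])
    )


@dataclass
class AnalysisConfig:
    """Everything one analysis run needs; ``seed`` is mandatory."""

    seed: int
    trees_csv: str | None = None
    plots_csv: str | None = None
    out_dir: str | None = None
    min_dbh: float = 10.0
    cutoff_abundance: int | None = None  # None → automated knee
    cutoff_biomass: int | None = None
    auto_knee: bool = True
    hellinger_biomass: bool = False
    alpha: float = 0.05
    n_perm: int = 999
    moran_alpha: float = 0.05
    moran_n_perm: int = 999
    truncation: float | None = None
    allow_unprojected: bool = False
    write_intermediates: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory (no silent clock seeding)")
        for a in (self.alpha, self.moran_alpha):
            if not 0 < a < 1:
                raise ValueError("alpha must be in (0, 1)")
        if not self.auto_knee and (
            self.cutoff_abundance is None or self.cutoff_biomass is None
        ):
            raise ValueError(
                "auto_knee is disabled: supply cutoff_abundance and cutoff_biomass"
            )

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def read_plots_csv(path, allow_unprojected: bool = False) -> pd.DataFrame:
    """Read the plot table (plot_id, x_m, y_m, covariates...), indexed by plot."""
    df = pd.read_csv(path, dtype={"plot_id": str})
    required = {"plot_id", *PLOTS_COORD_COLS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plots table missing columns: {sorted(missing)}")
    df = df.set_index("plot_id")
    if df.index.has_duplicates:
        raise ValueError("duplicate plot ids in plots table")
    if not allow_unprojected:
        validate_projected(df[list(PLOTS_COORD_COLS)].to_numpy())
    return df


@dataclass
class AnalysisResult:
    report: pd.DataFrame
    splits: dict[str, CommonRareSplit]
    eigenbasis: SpatialEigenbasis
    selections: dict[tuple[str, str, str], SelectionResult]
    partitions: dict[tuple[str, str], VariancePartition]
    config: AnalysisConfig


def _banner(stage: str, t0: float, **counts) -> None:
    extra = ", ".join(f"{k}={v}" for k, v in counts.items())
    log.info("[%s] done in %.2fs%s", stage, time.perf_counter() - t0, f" ({extra})" if extra else "")


def run_analysis(
    cfg: AnalysisConfig,
    trees: list | None = None,
    plots: pd.DataFrame | None = None,
) -> AnalysisResult:
    """Run the full pipeline and assemble the 18-row partition report.

    ``trees``/``plots`` may be passed in memory; otherwise they are read from
    the paths in the config.
    """
    t0 = time.perf_counter()
    if trees is None:
        if cfg.trees_csv is None:
            raise ValueError("no tree records: set trees_csv or pass records")
        trees = census_mod.read_trees_csv(cfg.trees_csv)
    if plots is None:
        if cfg.plots_csv is None:
            raise ValueError("no plot table: set plots_csv or pass a DataFrame")
        plots = read_plots_csv(cfg.plots_csv, cfg.allow_unprojected)

    # --- census ---
    records = census_mod.filter_census(trees, cfg.min_dbh)
    if not records:
        raise ValueError("census stage: no stems pass the DBH filter")
    model = AllometricModel()
    plot_ids = sorted(plots.index)
    abund = census_mod.build_matrix(records, "abundance", plot_ids=plot_ids)
    biom = census_mod.build_matrix(records, "biomass", model, plot_ids=plot_ids)
    if set(abund.plot_ids) - set(plots.index):
        raise ValueError("census stage: stems reference plots missing from the plot table")
    plots = plots.loc[abund.plot_ids]
    _banner("census", t0, stems=len(records), plots=abund.n_plots, species=abund.n_species)

    # --- common/rare splits (abundance- and biomass-ranked) ---
    t1 = time.perf_counter()
    split_ab = split_common_rare(abund, cutoff_rank=cfg.cutoff_abundance)
    split_bm = split_common_rare(biom, cutoff_rank=cfg.cutoff_biomass)
    _banner(
        "commonness",
        t1,
        common_ab=len(split_ab.common_ids),
        rare_trimmed_ab=len(split_ab.trimmed_rare_ids),
        common_bm=len(split_bm.common_ids),
    )

    # --- responses ---
    t1 = time.perf_counter()
    responses = build_responses(abund, biom, split_ab, split_bm, cfg.hellinger_biomass)
    _banner("attributes", t1, responses=len(responses))

    # --- spatial eigenfunctions ---
    t1 = time.perf_counter()
    coords = plots[list(PLOTS_COORD_COLS)].to_numpy(dtype=float)
    d = distance_matrix(coords)
    basis = pcnm(d, t=cfg.truncation, plot_ids=abund.plot_ids)
    basis = screen_eigenbasis(
        basis, d, cfg.moran_alpha, cfg.moran_n_perm, stage_rng(cfg.seed, "moran")
    )
    spa_df = pd.DataFrame(
        basis.retained_vectors(),
        index=abund.plot_ids,
        columns=[n for n, r in zip(basis.axis_names(), basis.retained) if r],
    )
    _banner(
        "spatial", t1, axes=basis.n_axes, retained=int(np.sum(basis.retained))
    )

    env_df = plots.drop(columns=list(PLOTS_COORD_COLS)).astype(float)

    # --- selection + partition per response ---
    t1 = time.perf_counter()
    selections: dict[tuple[str, str, str], SelectionResult] = {}
    partitions: dict[tuple[str, str], VariancePartition] = {}
    rows = []
    for attr in ATTRIBUTES:
        split = split_bm if attr in BIOMASS_SPLIT_ATTRIBUTES else split_ab
        for group in GROUPS:
            resp = responses[(attr, group)]
            y = getattr(resp, "values", None)
            if y is None:
                y = resp.as_column()
            sel_env = forward_select(
                y, env_df, cfg.alpha, cfg.n_perm,
                stage_rng(cfg.seed, f"select-env:{attr}:{group}"),
            )
            sel_spa = forward_select(
                y, spa_df, cfg.alpha, cfg.n_perm,
                stage_rng(cfg.seed, f"select-spa:{attr}:{group}"),
            )
            selections[(attr, group, "topography")] = sel_env
            selections[(attr, group, "space")] = sel_spa
            part = varpart(
                y,
                env_df[sel_env.selected_ids] if sel_env.selected_ids else None,
                spa_df[sel_spa.selected_ids] if sel_spa.selected_ids else None,
                n_perm=cfg.n_perm,
                rng=stage_rng(cfg.seed, f"varpart:{attr}:{group}"),
            )
            partitions[(attr, group)] = part
            rows.append(
                {
                    "attribute": attr,
                    "group": group,
                    "rank_range": _rank_range(group, split),
                    "n_species_group": _group_size(group, split, abund.n_species),
                    "topography": part.fraction_a,
                    "shared": part.fraction_b,
                    "space": part.fraction_c,
                    "not_explained": part.fraction_d,
                    "p_a": part.p_a,
                    "p_c": part.p_c,
                    "p_ab": part.p_ab,
                    "p_bc": part.p_bc,
                    "n_env_selected": part.n_env_selected,
                    "n_spa_selected": part.n_spa_selected,
                }
            )
    _banner("selection+partition", t1, rows=len(rows))

    report = pd.DataFrame(rows)
    result = AnalysisResult(report, {"abundance": split_ab, "biomass": split_bm},
                            basis, selections, partitions, cfg)
    if cfg.out_dir:
        _write_outputs(result, responses, spa_df, cfg)
    _banner("analysis", t0)
    return result


def _rank_range(group: str, split: CommonRareSplit) -> str:
    if group == "total":
        return "Total"
    if group == "common":
        return f"Common (1–{split.cutoff_rank})"
    lo, hi = split.trimmed_rare_rank_range
    return f"Rare ({lo}–{hi})"


def _group_size(group: str, split: CommonRareSplit, n_total: int) -> int:
    if group == "total":
        return n_total
    if group == "common":
        return len(split.common_ids)
    return len(split.trimmed_rare_ids)


def significance_code(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


ATTR_LABELS = {
    "std_richness": "Std. Richness",
    "abundance": "Abundance",
    "biomass": "Biomass",
    "c_incidence": "C. Incidence",
    "c_abundance": "C. Abundance",
    "c_biomass": "C. Biomass",
}


def format_report(report: pd.DataFrame, style: str = "text") -> str:
    """Render the partition report with table-style conventions.

    Percentages to one decimal; "-" for fractions whose predictor set ended
    up empty after selection; significance codes on the testable fractions
    (conditional tests for the pure fractions).
    """
    if style not in ("text", "csv"):
        raise ValueError("style must be 'text' or 'csv'")
    rows = []
    for r in report.itertuples(index=False):
        has_e, has_s = r.n_env_selected > 0, r.n_spa_selected > 0
        topo = f"{100 * r.topography:.1f}{significance_code(r.p_a)}" if has_e else "-"
        space = f"{100 * r.space:.1f}{significance_code(r.p_c)}" if has_s else "-"
        shared = f"{100 * r.shared:.1f}" if (has_e and has_s) else "-"
        rows.append(
            {
                "attribute": ATTR_LABELS[r.attribute],
                "group": r.rank_range,
                "topography_pct": topo,
                "shared_pct": shared,
                "space_pct": space,
                "not_explained_pct": f"{100 * r.not_explained:.2f}",
            }
        )
    out = pd.DataFrame(rows)
    if style == "csv":
        return out.to_csv(index=False)
    lines = [out.to_string(index=False)]
    lines.append("")
    lines.append("* p < 0.05; ** p < 0.01; *** p < 0.001; ns non-significant;")
    lines.append('"-" no variables selected for that predictor set.')
    return "\n".join(lines) + "\n"


def _write_outputs(result, responses, spa_df, cfg: AnalysisConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.report.to_csv(out / "report_raw.csv", index=False)
    (out / "report.csv").write_text(format_report(result.report, "csv"))
    (out / "report.txt").write_text(format_report(result.report, "text"))
    if cfg.write_intermediates:
        inter = out / "intermediates"
        inter.mkdir(exist_ok=True)
        spa_df.to_csv(inter / "pcnm_retained.csv", index_label="plot_id")
        for basis_name, split in result.splits.items():
            _split_report(split).to_csv(
                inter / f"split_{basis_name}.csv", index=False
            )
        sel_rows = []
        for (attr, group, which), sel in result.selections.items():
            for i, step in enumerate(sel.steps, start=1):
                sel_rows.append(
                    (attr, group, which, i, step.variable, step.pseudo_f,
                     step.p_value, step.cum_adj_r2)
                )
        pd.DataFrame(
            sel_rows,
            columns=["attribute", "group", "set", "step", "variable", "F", "p",
                     "cum_adj_r2"],
        ).to_csv(inter / "selection_steps.csv", index=False)


def _split_report(split: CommonRareSplit) -> pd.DataFrame:
    rows = []
    removed = set(split.rare_ids) - set(split.trimmed_rare_ids)
    for rank, sid in enumerate(split.common_ids + split.rare_ids, start=1):
        grp = (
            "common"
            if sid in set(split.common_ids)
            else ("removed" if sid in removed else "rare_trimmed")
        )
        rows.append((sid, rank, grp))
    return pd.DataFrame(rows, columns=["species_id", "rank", "group"])
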