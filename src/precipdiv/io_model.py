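"""Reading, validation and normalisation of community and metadata tables.

The community table is long format: one row per
(study, experiment, treatment, block, plot, species) with an abundance in
cover %, biomass g, or point-intercept hits.  The experiment metadata table
carries one row per experiment with the manipulation magnitude (delta_P, a
signed percent of mean annual precipitation), duration in years, background
climate (MAP, optionally PET), plot size and the life-history class of the
site's dominant species.

Abundance units are never converted between cover/biomass/hits: all
downstream metrics are unit-invariant within an experiment because log
response ratios cancel units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationReport",
    "COMMUNITY_COLUMNS",
    "META_COLUMNS",
    "read_community_table",
    "read_experiment_meta",
    "select_endpoint",
    "validate_dataset",
]


class SchemaError(ValueError):
    """Structural problem in an input table (missing column, duplicate key)."""


COMMUNITY_COLUMNS = [
    "study_id",
    "experiment_id",
    "treatment_id",
    "is_control",
    "block_id",
    "plot_id",
    "species_id",
    "abundance",
    "abundance_unit",
]
_COMMUNITY_OPTIONAL = ["year", "season"]

META_COLUMNS = [
    "study_id",
    "experiment_id",
    "site_id",
    "delta_P",
    "duration",
    "MAP",
    "plot_size",
]
_META_OPTIONAL = [
    "PET",
    "regional_area",
    "dominant_life_history",
    "latitude",
    "longitude",
    "peak_season",
]

_KEY_COLS = [
    "study_id",
    "experiment_id",
    "treatment_id",
    "block_id",
    "plot_id",
    "species_id",
]

VALID_UNITS = {"cover", "biomass", "hits"}


def _apply_dialect(df: pd.DataFrame, dialect: dict | None) -> pd.DataFrame:
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    return df


def read_community_table(path, dialect: dict | None = None) -> pd.DataFrame:
    """Load and validate a long-format community CSV.

    ``dialect`` maps canonical column names to the file's headers, e.g.
    ``{"species_id": "Taxon"}``.  Unknown columns are preserved unchanged.
    """
    df = _apply_dialect(pd.read_csv(path), dialect)
    missing = [c for c in COMMUNITY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"community table is missing required columns: {missing}")

    df["abundance"] = pd.to_numeric(df["abundance"])
    bad = df["abundance"] < 0
    if bad.any():
        row = df.loc[bad.idxmax()]
        key = tuple(row[c] for c in _KEY_COLS)
        raise ValueError(f"negative abundance at row key {key}")

    if df["is_control"].dtype != bool:
        df["is_control"] = (
            df["is_control"].astype(str).str.strip().str.lower().isin({"true", "1", "yes", "t"})
        )

    unknown_units = set(df["abundance_unit"].unique()) - VALID_UNITS
    if unknown_units:
        raise SchemaError(f"unknown abundance_unit values: {sorted(unknown_units)}")

    key_cols = _KEY_COLS + [c for c in ("year",) if c in df.columns]
    dup = df.duplicated(subset=key_cols, keep=False)
    if dup.any():
        dups = df.loc[dup, key_cols].drop_duplicates().head(5)
        raise SchemaError(
            "duplicated (study, experiment, treatment, block, plot, species, year) keys:\n"
            + dups.to_string(index=False)
        )
    return df


def read_experiment_meta(path, dialect: dict | None = None) -> pd.DataFrame:
    """Load the per-experiment covariate table; derive direction from sign(delta_P)."""
    df = _apply_dialect(pd.read_csv(path), dialect)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"experiment metadata is missing required columns: {missing}")
    for col in ("delta_P", "duration", "MAP", "plot_size"):
        df[col] = pd.to_numeric(df[col])
    if (df["delta_P"] == 0).any():
        bad = df.loc[df["delta_P"] == 0, "experiment_id"].tolist()
        raise ValueError(f"delta_P = 0 for experiments {bad}; manipulations must be nonzero")
    if ((df["MAP"] <= 0) | (df["MAP"] >= 12000)).any():
        bad = df.loc[(df["MAP"] <= 0) | (df["MAP"] >= 12000), "experiment_id"].tolist()
        raise ValueError(f"MAP outside plausible range (0, 12000) for experiments {bad}")
    df["direction"] = np.where(df["delta_P"] > 0, "increase", "decrease")
    dup = df.duplicated(subset=["study_id", "experiment_id"], keep=False)
    if dup.any():
        raise SchemaError("duplicate (study_id, experiment_id) rows in metadata")
    return df


def select_endpoint(community: pd.DataFrame, meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Keep only the final-year, peak-season rows of each experiment.

    Multi-year time series are reduced to their endpoint (maximum recorded
    year per experiment).  If several seasons were sampled in that year, the
    season flagged as ``peak_season`` in the metadata is kept; without a flag
    the season with the highest summed abundance wins.  Tables without year
    or season columns pass through unchanged.
    """
    df = community
    if "year" in df.columns and df["year"].notna().any():
        max_year = df.groupby("experiment_id")["year"].transform("max")
        df = df[df["year"] == max_year]
    if "season" in df.columns and df["season"].notna().any():
        flagged = {}
        if meta is not None and "peak_season" in meta.columns:
            flagged = meta.set_index("experiment_id")["peak_season"].dropna().to_dict()
        keep_parts = []
        for exp_id, grp in df.groupby("experiment_id", sort=False):
            seasons = grp["season"].dropna().unique()
            if len(seasons) <= 1:
                keep_parts.append(grp)
                continue
            if exp_id in flagged and flagged[exp_id] in seasons:
                peak = flagged[exp_id]
            else:
                peak = grp.groupby("season")["abundance"].sum().idxmax()
            keep_parts.append(grp[grp["season"] == peak])
        df = pd.concat(keep_parts, ignore_index=False)
    return df.reset_index(drop=True)


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)  # (severity, key, message)
    n_studies: int = 0
    n_experiments: int = 0
    n_treatments: int = 0
    n_plots: int = 0

    @property
    def n_errors(self) -> int:
        return sum(1 for sev, *_ in self.errors if sev == "error")

    @property
    def n_warnings(self) -> int:
        return sum(1 for sev, *_ in self.errors if sev == "warning")

    def to_json(self) -> str:
        return json.dumps(
            {
                "errors": [
                    {"severity": s, "key": str(k), "message": m} for s, k, m in self.errors
                ],
                "n_studies": self.n_studies,
                "n_experiments": self.n_experiments,
                "n_treatments": self.n_treatments,
                "n_plots": self.n_plots,
            },
            indent=2,
        )


def validate_dataset(
    community: pd.DataFrame, meta: pd.DataFrame, n_ref: int = 3
) -> ValidationReport:
    """Cross-check community and metadata tables; report all violations.

    Violations are collected with a severity rather than raised, so a single
    pass reports every problem.  Treatments with fewer replicate plots than
    the rarefaction depth draw a warning (their site-scale metrics will be
    missing), not an error.
    """
    rep = ValidationReport()
    rep.n_studies = community["study_id"].nunique()
    rep.n_experiments = community["experiment_id"].nunique()
    rep.n_treatments = community.groupby(["experiment_id", "treatment_id"]).ngroups
    rep.n_plots = community.groupby(
        ["experiment_id", "treatment_id", "block_id", "plot_id"]
    ).ngroups

    for exp_id, grp in community.groupby("experiment_id"):
        controls = grp.loc[grp["is_control"], "treatment_id"].unique()
        if len(controls) == 0:
            rep.errors.append(("error", exp_id, "experiment has no control treatment"))
        elif len(controls) > 1:
            rep.errors.append(
                ("error", exp_id, f"experiment has {len(controls)} control treatments")
            )
        if grp["abundance_unit"].nunique() > 1:
            rep.errors.append(("error", exp_id, "mixed abundance units within experiment"))
        for trt_id, tgrp in grp.groupby("treatment_id"):
            n_plots = tgrp.groupby(["block_id", "plot_id"]).ngroups
            if n_plots < n_ref:
                rep.errors.append(
                    (
                        "warning",
                        (exp_id, trt_id),
                        f"insufficient replicates ({n_plots} < {n_ref}) for site-scale metrics",
                    )
                )

    meta_exps = set(meta["experiment_id"])
    comm_exps = set(community["experiment_id"])
    for exp_id in sorted(meta_exps - comm_exps):
        rep.errors.append(
            ("error", exp_id, "metadata references experiment absent from community table")
        )
    for exp_id in sorted(comm_exps - meta_exps):
        rep.errors.append(("warning", exp_id, "experiment has no metadata row"))
    return rep
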