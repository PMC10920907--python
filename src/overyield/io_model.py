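"""Data model, table readers/validators, monoculture referencing, and filters.

Long productivity tables are held as pandas DataFrames with columns
``site, plot, year, species, value`` plus a measurement ``kind`` tag
(one of :data:`MEASUREMENT_KINDS`).  ``year`` is the 1-based experiment
year (year 1 = first growing season after establishment); calendar
years in raw files can be shifted via a per-site establishment year.

Composition tables carry the sown/planted proportions ``p_i`` per plot
(columns ``site, plot, species, proportion``); plot richness is the
count of sown species and a monoculture is a single species at p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MEASUREMENT_KINDS = ("biomass", "ba_increment", "ba_accumulated")

PRODUCTIVITY_COLUMNS = ["site", "plot", "year", "species", "value"]
COMPOSITION_COLUMNS = ["site", "plot", "species", "proportion"]

#: proportions must sum to one per plot within this tolerance
COMPOSITION_TOL = 1e-9


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """Rows violate a data-model invariant (negative value, duplicate key...)."""


@dataclass
class LoadReport:
    """Outcome of loading/validating one table."""

    path: str
    n_records: int
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _read_delimited(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def read_long_table(path, kind: str = "biomass", strict: bool = True):
    """Read a long productivity table (CSV/TSV by extension).

    Returns ``(records, report)``.  Malformed rows are reported with
    1-based data line numbers (header = line 1).  With ``strict=True``
    any error raises; otherwise offending rows are dropped and listed
    in the report.
    """
    if kind not in MEASUREMENT_KINDS:
        raise ValueError(f"unknown measurement kind {kind!r}; expected one of {MEASUREMENT_KINDS}")
    df = _read_delimited(path)
    missing = [c for c in PRODUCTIVITY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    df = df[PRODUCTIVITY_COLUMNS].copy()
    report = LoadReport(path=str(path), n_records=0)
    lineno = df.index.to_numpy() + 2  # header is line 1

    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    df["year"] = pd.to_numeric(df["year"], errors="coerce")

    bad = df["value"].isna() | df["year"].isna()
    for ln, row in zip(lineno[bad], df[bad].itertuples(index=False)):
        report.errors.append(f"line {ln}: non-numeric value/year in {tuple(row)}")

    # negative increments are a legal derived quantity; raw loads must be >= 0
    neg = (df["value"] < 0) & ~bad
    if kind != "ba_increment":
        for ln, row in zip(lineno[neg], df[neg].itertuples(index=False)):
            key = (row.site, row.plot, int(row.year), row.species)
            report.errors.append(f"line {ln}: negative value for (site,plot,year,species)={key}")
        bad = bad | neg

    nonpos_year = (df["year"] < 1) & ~df["year"].isna()
    for ln in lineno[nonpos_year & ~bad]:
        report.errors.append(f"line {ln}: experiment year < 1")
    bad = bad | nonpos_year

    dup = df.duplicated(subset=["site", "plot", "year", "species"], keep=False) & ~bad
    if dup.any():
        for key, grp in df[dup].groupby(["site", "plot", "year", "species"]):
            lns = ", ".join(str(x) for x in lineno[grp.index])
            report.errors.append(f"duplicate key {key} at lines {lns}")
        bad = bad | df.duplicated(subset=["site", "plot", "year", "species"], keep="first")

    if report.errors and strict:
        raise ValidationError(f"{path}: " + "; ".join(report.errors))

    records = df[~bad].reset_index(drop=True)
    records["year"] = records["year"].astype(int)
    records.attrs["kind"] = kind
    report.n_records = len(records)
    return records, report


def read_composition(path, strict: bool = True):
    """Read a sown/planted composition table; validates Σp = 1 per plot."""
    df = _read_delimited(path)
    missing = [c for c in COMPOSITION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    df = df[COMPOSITION_COLUMNS].copy()
    df["proportion"] = pd.to_numeric(df["proportion"], errors="coerce")
    report = LoadReport(path=str(path), n_records=len(df))
    bad_p = df["proportion"].isna() | (df["proportion"] <= 0) | (df["proportion"] > 1)
    for row in df[bad_p].itertuples(index=False):
        report.errors.append(f"proportion out of (0,1] for {(row.site, row.plot, row.species)}")
    sums = df.groupby(["site", "plot"])["proportion"].sum()
    off = sums[(sums - 1.0).abs() > COMPOSITION_TOL]
    for key, s in off.items():
        report.errors.append(f"proportions sum to {s!r} != 1 in plot {key}")
    if report.errors and strict:
        raise ValidationError(f"{path}: " + "; ".join(report.errors))
    return df, report


def plot_richness(composition: pd.DataFrame) -> pd.DataFrame:
    """Sown richness per (site, plot): number of species in the composition."""
    sr = (
        composition.groupby(["site", "plot"])["species"]
        .nunique()
        .rename("richness")
        .reset_index()
    )
    return sr


def monoculture_plots(composition: pd.DataFrame) -> pd.DataFrame:
    """Subset of composition rows that are monocultures (1 species, p = 1)."""
    sr = plot_richness(composition)
    mono = composition.merge(sr, on=["site", "plot"])
    return mono[mono["richness"] == 1].drop(columns="richness")


def build_monoculture_reference(records: pd.DataFrame, composition: pd.DataFrame):
    """Mean monoculture performance M_i per (site, year, species).

    M_i is the arithmetic mean over all replicate monoculture plots of
    that species at that site and year (``n_reps`` reports how many).
    Species that appear in a mixture but have no same-year monoculture
    at that site are returned in the ``uncomputable`` list — their
    log response ratios will be undefined downstream.

    Returns ``(reference, uncomputable)`` where ``reference`` has columns
    ``site, year, species, M, n_reps``.
    """
    mono = monoculture_plots(composition)
    mono_rec = records.merge(mono[["site", "plot", "species"]], on=["site", "plot", "species"])
    reference = (
        mono_rec.groupby(["site", "year", "species"], as_index=False)
        .agg(M=("value", "mean"), n_reps=("value", "size"))
        .sort_values(["site", "year", "species"])
        .reset_index(drop=True)
    )

    sr = plot_richness(composition)
    mixtures = composition.merge(sr, on=["site", "plot"])
    mixtures = mixtures[mixtures["richness"] > 1]
    mix_rec = records.merge(mixtures[["site", "plot", "species"]], on=["site", "plot", "species"])
    need = mix_rec[["site", "year", "species"]].drop_duplicates()
    have = reference[["site", "year", "species"]]
    gaps = need.merge(have, on=["site", "year", "species"], how="left", indicator=True)
    uncomputable = (
        gaps[gaps["_merge"] == "left_only"]
        .drop(columns="_merge")
        .sort_values(["site", "year", "species"])
        .reset_index(drop=True)
    )
    return reference, uncomputable


def derive_increment(accumulated: pd.DataFrame):
    """Annual basal-area increment from an accumulated basal-area series.

    For each (site, plot, species) series ordered by year,
    ``increment(t) = accumulated(t) - accumulated(t_prev)``; when the
    gap between measured years exceeds one year the difference is
    annualized (divided by the gap) so the derived kind is always
    "per year".  The first measured year of a series yields no record.

    Decreasing accumulated series are biologically possible (mortality
    outpacing growth); negative increments are kept and flagged with a
    warning — the lnRR domain rules exclude them later.

    Returns ``(increments, warnings)``.
    """
    if accumulated.attrs.get("kind", "ba_accumulated") != "ba_accumulated":
        raise ValueError("derive_increment expects kind='ba_accumulated' records")
    out = []
    warnings: list[str] = []
    for (site, plot, species), grp in accumulated.groupby(["site", "plot", "species"]):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy()
        if np.any(np.diff(years) <= 0):
            raise ValidationError(f"non-increasing years in series {(site, plot, species)}")
        vals = grp["value"].to_numpy(dtype=float)
        if len(vals) < 2:
            continue
        gap = np.diff(years)
        inc = np.diff(vals) / gap
        for y, v in zip(years[1:], inc):
            if v < 0:
                warnings.append(
                    f"decreasing accumulated basal area for {(site, plot, species)} at year {y}"
                )
            out.append((site, plot, int(y), species, v))
    increments = pd.DataFrame(out, columns=PRODUCTIVITY_COLUMNS)
    increments.attrs["kind"] = "ba_increment"
    return increments, warnings


def apply_year_window(records: pd.DataFrame, system: str):
    """Keep the analysis year window: grassland years 1–10; forest years 3–13.

    Grassland analyses use up to ten years of data; forest analyses use
    up to eleven retained years after dropping the first two experiment
    years (re-planting commonly disturbs those).  Returns
    ``(kept, n_removed)``.
    """
    if system == "grassland":
        keep = (records["year"] >= 1) & (records["year"] <= 10)
    elif system == "forest":
        keep = (records["year"] >= 3) & (records["year"] <= 13)
    else:
        raise ValueError(f"unknown system {system!r}; expected 'grassland' or 'forest'")
    kept = records[keep].reset_index(drop=True)
    kept.attrs["kind"] = records.attrs.get("kind")
    return kept, int((~keep).sum())


def map_calendar_years(records: pd.DataFrame, establishment: dict) -> pd.DataFrame:
    """Convert calendar years to 1-based experiment years.

    ``establishment`` maps site id -> establishment calendar year (year
    before the first growing season); experiment year = calendar -
    establishment.
    """
    missing = set(records["site"].unique()) - set(establishment)
    if missing:
        raise ValidationError(f"no establishment year for site(s) {sorted(missing)}")
    out = records.copy()
    out["year"] = out["year"] - out["site"].map(establishment)
    if (out["year"] < 1).any():
        raise ValidationError("mapped experiment year < 1; check establishment years")
    out.attrs["kind"] = records.attrs.get("kind")
    return out
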