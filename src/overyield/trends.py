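"""Mixed-effects temporal-trend models for overyielding responses.

Species-level model: species lnRR regressed on the two trait strategy
axes (PC1, PC2), log2 sown richness, ln experiment year, and the
trait x richness, trait x year and richness x year interactions, with a
random intercept per species-in-plot (SP_PlotID), a random intercept
per site, random site slopes for richness, traits and year, and AR(1)
residual correlation over years within each species-in-plot series.

Community-level model: a community response (community lnRR, net /
complementarity / selection effect, or log10 productivity) on log2
richness, ln year and their interaction, with plot and site random
intercepts, site slopes for richness and year, and AR(1) within plot.

Transform conventions: richness enters as log2(SR), year as ln(year);
the strategy scores are already unit-variance composites of log10
traits and enter untransformed.  P values are one-sided F tests
(all fixed terms here are single-df, so F = t²).

If the full random structure fails to converge the fit walks a
documented fallback ladder — drop site trait slopes, then drop all
site slopes, then drop AR(1), then intercepts only — recording each
step in the fit log.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from overyield.lmm import LMMFit, RandomComponent, fit_lmm

SPECIES_FIXED_TERMS = [
    "PC1", "PC2", "log2SR", "lnyear",
    "PC1:log2SR", "PC2:log2SR", "PC1:lnyear", "PC2:lnyear", "log2SR:lnyear",
]
COMMUNITY_FIXED_TERMS = ["log2SR", "lnyear", "log2SR:lnyear"]


def _codes(values) -> np.ndarray:
    if isinstance(values, list) and values and isinstance(values[0], tuple):
        values = ["/".join(map(str, v)) for v in values]
    return pd.factorize(pd.Series(list(values)))[0]


def _species_design(df: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    X["Intercept"] = 1.0
    X["PC1"] = df["PC1"].to_numpy(float)
    X["PC2"] = df["PC2"].to_numpy(float)
    X["log2SR"] = np.log2(df["richness"].to_numpy(float))
    X["lnyear"] = np.log(df["year"].to_numpy(float))
    X["PC1:log2SR"] = X["PC1"] * X["log2SR"]
    X["PC2:log2SR"] = X["PC2"] * X["log2SR"]
    X["PC1:lnyear"] = X["PC1"] * X["lnyear"]
    X["PC2:lnyear"] = X["PC2"] * X["lnyear"]
    X["log2SR:lnyear"] = X["log2SR"] * X["lnyear"]
    return X


def _community_design(df: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    X["Intercept"] = 1.0
    X["log2SR"] = np.log2(df["richness"].to_numpy(float))
    X["lnyear"] = np.log(df["year"].to_numpy(float))
    X["log2SR:lnyear"] = X["log2SR"] * X["lnyear"]
    return X


def _site_slope_components(df, X, slope_cols, site_codes):
    comps = []
    for col in slope_cols:
        comps.append(RandomComponent(f"site_slope[{col}]", site_codes, X[col].to_numpy()))
    return comps


def _ladder_fit(y, X, blocks, ladder, series, times, ddf_method, log):
    last_err = None
    for label, comps, use_ar1 in ladder:
        try:
            fit = fit_lmm(
                y, X, blocks, comps, series=series, times=times, ar1=use_ar1,
                ddf_method=ddf_method,
            )
        except np.linalg.LinAlgError as err:
            log.append(f"structure '{label}' failed: {err}")
            last_err = err
            continue
        if fit.converged:
            fit.log[:0] = log + [f"converged with structure '{label}'"]
            return fit
        log.append(f"structure '{label}' did not converge")
    raise RuntimeError(f"no trend-model structure converged; last error: {last_err}")


def fit_species_trend(
    species_table: pd.DataFrame,
    scores: pd.DataFrame,
    ddf_method: str = "satterthwaite",
    ar1: bool = True,
    site_slopes: bool = True,
) -> LMMFit:
    """Species-level overyielding trend model.

    ``species_table`` is the per (site, plot, year, species) metrics
    table (mixtures, finite lnRR, exclusions already applied);
    ``scores`` maps species id -> PC1, PC2 strategy scores.
    """
    df = species_table[~species_table["excluded"]].copy() if "excluded" in species_table else species_table.copy()
    df = df[np.isfinite(df["lnrr"])]
    df = df.merge(scores[["PC1", "PC2"]], left_on="species", right_index=True, how="inner")
    if df.empty:
        raise ValueError("no usable species lnRR rows")
    if df["year"].nunique() < 2:
        raise ValueError("need at least two experiment years")

    X = _species_design(df)
    y = df["lnrr"].to_numpy(float)
    site_codes = _codes(df["site"])
    sp_plot = _codes(list(zip(df["site"], df["plot"], df["species"])))
    n_sites = site_codes.max() + 1

    log: list[str] = []
    sp_plot_ic = RandomComponent("sp_plot", sp_plot, np.ones(len(df)))
    if n_sites < 2:
        log.append("single site: site random terms dropped")
        base = [sp_plot_ic]
        full = base
        no_trait_slopes = base
    else:
        site_ic = RandomComponent("site", site_codes, np.ones(len(df)))
        trait_slopes = _site_slope_components(df, X, ["PC1", "PC2"], site_codes)
        env_slopes = _site_slope_components(df, X, ["log2SR", "lnyear"], site_codes)
        full = [site_ic, sp_plot_ic] + (env_slopes + trait_slopes if site_slopes else [])
        no_trait_slopes = [site_ic, sp_plot_ic] + (env_slopes if site_slopes else [])
        base = [site_ic, sp_plot_ic]

    series = sp_plot
    times = df["year"].to_numpy(float)
    ladder = [
        ("full", full, ar1),
        ("no site trait slopes", no_trait_slopes, ar1),
        ("no AR(1)", no_trait_slopes, False),
        ("intercepts only", base, False),
    ]
    # drop duplicate ladder rungs (e.g. when site_slopes=False)
    seen = set()
    ladder = [r for r in ladder if not (tuple(id(c) for c in r[1]) + (r[2],)) in seen
              and not seen.add(tuple(id(c) for c in r[1]) + (r[2],))]
    return _ladder_fit(y, X, site_codes, ladder, series, times, ddf_method, log)


def fit_community_trend(
    community_table: pd.DataFrame,
    response: str = "community_lnrr",
    ddf_method: str = "satterthwaite",
    ar1: bool = True,
    site_slopes: bool = True,
) -> LMMFit:
    """Community-level trend model for one response column.

    ``response`` is one of ``community_lnrr``, ``NE``, ``CE``, ``SE``
    or ``productivity`` (the latter fitted on the log10 scale; the
    table must then carry a positive ``productivity`` column).
    """
    df = community_table.copy()
    if response == "productivity":
        df = df[df["productivity"] > 0]
        y = np.log10(df["productivity"].to_numpy(float))
    else:
        df = df[np.isfinite(df[response])]
        y = df[response].to_numpy(float)
    if df.empty:
        raise ValueError(f"no usable rows for response {response!r}")

    X = _community_design(df)
    site_codes = _codes(df["site"])
    plot_codes = _codes(list(zip(df["site"], df["plot"])))
    n_sites = site_codes.max() + 1

    log: list[str] = []
    plot_ic = RandomComponent("plot", plot_codes, np.ones(len(df)))
    if n_sites < 2:
        log.append("single site: site random terms dropped")
        full = [plot_ic]
        no_slopes = [plot_ic]
        base = [plot_ic]
    else:
        site_ic = RandomComponent("site", site_codes, np.ones(len(df)))
        slopes = _site_slope_components(df, X, ["log2SR", "lnyear"], site_codes)
        full = [site_ic, plot_ic] + (slopes if site_slopes else [])
        no_slopes = [site_ic, plot_ic]
        base = [site_ic, plot_ic]

    ladder = [
        ("full", full, ar1),
        ("no site slopes", no_slopes, ar1),
        ("no AR(1)", no_slopes, False),
        ("intercepts only", base, False),
    ]
    return _ladder_fit(
        y, X, site_codes, ladder, plot_codes, df["year"].to_numpy(float), ddf_method, log
    )
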