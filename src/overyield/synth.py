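"""Seedable synthetic biodiversity-experiment generator with known truth.

Emulates multi-site grassland and forest diversity experiments — a
richness gradient with replicated monocultures, multi-year
measurements, trait-correlated overyielding that shifts over time, and
AR(1) residual noise — so that every pipeline stage can be exercised
against ground truth.

The generative model, all on the natural-log scale for productivity:

* each species s carries a latent acquisitiveness ``g_s ~ N(0, 1)``
  (high = fast/acquisitive) and an independent nutrient-economy axis
  ``h_s ~ N(0, 1)``; log10 traits are linear in (g, h) plus noise with
  the economics-spectrum sign pattern (SLA, SRL, LNC, RNC increase
  with g; LDMC, RTD decrease);
* monoculture productivity declines faster for acquisitive species
  (species-specific pathogen build-up):
  ``ln M_s(t) = mu_s + site + (delta0 + delta1 * g_s) * ln t``,
  delta1 < 0;
* species overyielding in mixture follows the surface
  ``beta_s(t, SR) = b0 + b1*s + b2*s*ln t + b3*log2(SR)*ln t`` where
  ``s`` is the species' trait-PC1 strategy score (the oriented
  unit-variance first axis of the complete trait matrix — the covariate
  the trend models regress on, so b1 and b2 are the estimands of the
  fitted coefficients); a mixture species observes
  ``ln O = ln p_s + ln M_s(t) + beta + noise``;
* residual noise is stationary AR(1) in ln-space (marginal sd
  ``sigma``, autocorrelation ``phi``) per plot-species series.

Forests accumulate basal area: mixture/monoculture effects act on the
annual increment and mortality events knock a random fraction off the
accumulated series (so accumulated series may decrease).

Defaults are fixed study conditions, not tuning knobs; see the
methods note for their rationale.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from overyield.io_model import PRODUCTIVITY_COLUMNS
from overyield.traits import TRAITS

#: log10-scale trait means / sds for a realistic herbaceous+woody pool
TRAIT_MEANS = {"SLA": 1.30, "LNC": 1.30, "LDMC": 1.40, "SRL": 2.00, "RNC": 1.08, "RTD": -0.46}
TRAIT_SDS = {"SLA": 0.20, "LNC": 0.12, "LDMC": 0.15, "SRL": 0.25, "RNC": 0.12, "RTD": 0.15}
#: loadings of the acquisitiveness axis g on each log10 trait (sign = spectrum)
G_LOADINGS = {"SLA": 0.88, "LNC": 0.35, "LDMC": -0.85, "SRL": 0.85, "RNC": 0.30, "RTD": -0.85}
#: loadings of the independent nutrient axis h (nitrogen economy)
H_LOADINGS = {"SLA": 0.00, "LNC": 0.80, "LDMC": 0.00, "SRL": 0.00, "RNC": 0.85, "RTD": 0.00}


@dataclass
class GeneratorTruth:
    """Ground truth serialized alongside every simulated dataset."""

    g: pd.Series                      # latent acquisitiveness per species
    h: pd.Series                      # latent nutrient-economy axis
    mu: pd.Series                     # ln monoculture baseline per species
    strategy: pd.Series = None        # trait-PC1 score driving the overyield surface
    b0: float = 0.10                  # baseline overyielding
    b1: float = 0.15                  # acquisitive species overyield early
    b2: float = -0.05                 # acquisitive advantage erodes over ln(year)
    b3: float = 0.03                  # richness strengthens overyielding over time
    delta0: float = -0.02             # common monoculture drift on ln(year)
    delta1: float = -0.05             # extra decline for acquisitive monocultures
    sigma: float = 0.20               # residual sd, ln scale
    phi: float = 0.50                 # AR(1) autocorrelation of residuals
    site_sd: float = 0.30             # site intercept sd, ln scale
    mortality_hazard: float = 0.0     # per species-plot-year (forest)
    g_loadings: dict = field(default_factory=lambda: dict(G_LOADINGS))
    h_loadings: dict = field(default_factory=lambda: dict(H_LOADINGS))

    def beta(self, s, year, richness):
        """Expected species lnRR beta_s(t, SR) for strategy score(s) s.

        The surface is parametrized on the species' trait-PC1 strategy
        score (unit variance over the pool), the covariate the trend
        models actually regress on, so b1/b2 are the estimands of the
        fitted PC1 and PC1 x ln(year) coefficients.
        """
        lnt = np.log(year)
        return self.b0 + self.b1 * s + self.b2 * s * lnt + self.b3 * np.log2(richness) * lnt

    def to_json(self, path):
        d = dataclasses.asdict(self)
        for k in ("g", "h", "mu", "strategy"):
            d[k] = {str(s): float(v) for s, v in d[k].items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


def make_species_pool(n_species: int = 200, seed: int = 0, missingness: float = 0.15,
                      g_loadings: dict | None = None, h_loadings: dict | None = None,
                      **truth_kwargs):
    """Draw a species pool: trait matrix (optionally with gaps) + truth.

    Each log10 trait is ``mean + sd * (w*g + v*h + u*e)`` with
    ``u = sqrt(1 - w² - v²)`` so the latent axes explain a fixed share
    of every trait's variance.  ``missingness`` masks measured cells at
    random (never a species' last remaining trait).  Returns
    ``(trait_matrix, truth)``; the matrix is in raw trait units.
    """
    if n_species < 8:
        raise ValueError("n_species must be >= 8")
    w = dict(G_LOADINGS if g_loadings is None else g_loadings)
    v = dict(H_LOADINGS if h_loadings is None else h_loadings)
    if set(w) != set(TRAITS) or set(v) != set(TRAITS):
        raise ValueError(f"loading vectors must name exactly the traits {TRAITS}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    species = [f"sp{i:03d}" for i in range(1, n_species + 1)]
    g = rng.standard_normal(n_species)
    h = rng.standard_normal(n_species)

    logm = np.empty((n_species, len(TRAITS)))
    for j, t in enumerate(TRAITS):
        u2 = 1.0 - w[t] ** 2 - v[t] ** 2
        if u2 < 0:
            raise ValueError(f"loadings for {t} exceed unit variance (w^2 + v^2 > 1)")
        e = rng.standard_normal(n_species)
        logm[:, j] = TRAIT_MEANS[t] + TRAIT_SDS[t] * (w[t] * g + v[t] * h + np.sqrt(u2) * e)
    matrix = pd.DataFrame(10.0**logm, index=pd.Index(species, name="species"), columns=TRAITS)

    # the strategy score driving overyielding dynamics: the oriented PC1 of
    # the complete trait matrix (what the trend models regress on)
    from overyield.traits import strategy_axes

    strategy = strategy_axes(matrix).scores["PC1"]

    if missingness > 0:
        mask = rng.random(matrix.shape) < missingness
        # keep at least one measured trait per species
        for i in np.flatnonzero(mask.all(axis=1)):
            mask[i, rng.integers(len(TRAITS))] = False
        matrix = matrix.mask(mask)

    idx = pd.Index(species, name="species")
    mu = pd.Series(rng.normal(0.0, 0.4, n_species), index=idx)
    truth = GeneratorTruth(
        g=pd.Series(g, index=idx), h=pd.Series(h, index=idx), mu=mu,
        strategy=strategy, g_loadings=w, h_loadings=v, **truth_kwargs,
    )
    return matrix, truth


def _ar1_noise(rng, n_series, n_years, sigma, phi):
    """Stationary AR(1) paths, shape (n_series, n_years), marginal sd sigma."""
    eps = np.empty((n_series, n_years))
    eps[:, 0] = rng.normal(0.0, sigma, n_series)
    innov_sd = sigma * np.sqrt(1.0 - phi**2)
    for t in range(1, n_years):
        eps[:, t] = phi * eps[:, t - 1] + rng.normal(0.0, innov_sd, n_series)
    return eps


def _site_layout(rng, truth, site, pool, richness_levels, plots_per_richness, mono_reps,
                 disjoint_mixtures=False):
    """Plot compositions for one site: replicated monocultures + mixtures.

    With ``disjoint_mixtures`` the mixture plots partition a shuffled
    species pool so no species occurs in two mixtures of the same site
    (requires a pool at least as large as the summed mixture richness);
    otherwise each plot draws its species independently, so species
    recur across plots as in most real designs.
    """
    comp_rows = []
    plots = []
    for s in pool:
        for r in range(mono_reps):
            plot = f"{site}_mono_{s}_{r+1}"
            comp_rows.append((site, plot, s, 1.0))
            plots.append((plot, [s]))
    mix_levels = [sr for sr in richness_levels if sr >= 2 for _ in range(plots_per_richness)]
    if disjoint_mixtures:
        need = sum(mix_levels)
        if need > len(pool):
            raise ValueError(
                f"disjoint mixtures need {need} species but the site pool has {len(pool)}"
            )
        shuffled = list(rng.permutation(pool))
    taken = 0
    for j, sr in enumerate(mix_levels):
        plot = f"{site}_mix{sr:02d}_{j+1}"
        if disjoint_mixtures:
            chosen = shuffled[taken:taken + sr]
            taken += sr
        else:
            chosen = list(rng.choice(pool, size=sr, replace=False))
        for s in chosen:
            comp_rows.append((site, plot, s, 1.0 / sr))
        plots.append((plot, chosen))
    return comp_rows, plots


def simulate_grassland(
    truth: GeneratorTruth,
    n_sites: int = 20,
    richness_levels=(1, 2, 4, 8, 16),
    plots_per_richness: int = 2,
    mono_reps: int = 2,
    n_years: int = 10,
    species_per_site: int = 16,
    seed: int = 0,
    disjoint_mixtures: bool = False,
):
    """Simulate a multi-site grassland experiment (biomass, g m⁻²).

    Each site draws ``species_per_site`` species from the pool, plants
    ``mono_reps`` monocultures of every one of them plus
    ``plots_per_richness`` mixture plots per richness level (equal
    sowing, p = 1/SR), and is measured annually for ``n_years`` years.
    Returns ``(productivity, composition)`` long tables; kind
    ``biomass``; baseline scaled to a few hundred g m⁻².
    """
    return _simulate(truth, "grassland", n_sites, richness_levels, plots_per_richness,
                     mono_reps, n_years, species_per_site, seed, disjoint_mixtures)


def simulate_forest(
    truth: GeneratorTruth,
    n_sites: int = 10,
    richness_levels=(1, 2, 4, 8),
    plots_per_richness: int = 2,
    mono_reps: int = 2,
    n_years: int = 13,
    species_per_site: int = 8,
    seed: int = 0,
    disjoint_mixtures: bool = False,
):
    """Simulate a tree-diversity experiment (accumulated basal area).

    Mixture and monoculture effects act on the annual basal-area
    increment; accumulated series sum the increments and mortality
    events (``truth.mortality_hazard`` per species-plot-year) remove a
    random 20–60% of standing basal area, so accumulated series can
    decrease.  Returns ``(productivity, composition)`` with kind
    ``ba_accumulated``.
    """
    return _simulate(truth, "forest", n_sites, richness_levels, plots_per_richness,
                     mono_reps, n_years, species_per_site, seed, disjoint_mixtures)


def _simulate(truth, system, n_sites, richness_levels, plots_per_richness,
              mono_reps, n_years, species_per_site, seed, disjoint_mixtures=False):
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x51317 if system == "grassland" else 0xF0357]))
    pool_all = truth.g.index.to_numpy()
    if species_per_site > len(pool_all):
        raise ValueError("species_per_site exceeds the species pool")
    if max(richness_levels) > species_per_site:
        raise ValueError("largest richness level exceeds species_per_site")

    baseline = np.log(300.0) if system == "grassland" else np.log(20.0)
    years = np.arange(1, n_years + 1)
    lnt = np.log(years)

    comp_rows_all = []
    prod_rows = []
    for i in range(n_sites):
        site = f"s{i+1:02d}"
        site_eff = rng.normal(0.0, truth.site_sd)
        pool = rng.choice(pool_all, size=species_per_site, replace=False)
        comp_rows, plots = _site_layout(rng, truth, site, pool, richness_levels,
                                        plots_per_richness, mono_reps, disjoint_mixtures)
        comp_rows_all.extend(comp_rows)

        series = [(plot, s, len(members)) for plot, members in plots for s in members]
        eps = _ar1_noise(rng, len(series), n_years, truth.sigma, truth.phi)
        for (plot, s, sr), noise in zip(series, eps):
            g_s = truth.g[s]
            mu_s = baseline + truth.mu[s] + site_eff
            ln_mono = mu_s + (truth.delta0 + truth.delta1 * g_s) * lnt
            if sr == 1:
                ln_flux = ln_mono + noise
            else:
                beta = truth.beta(truth.strategy[s], years, sr)
                ln_flux = np.log(1.0 / sr) + ln_mono + beta + noise
            flux = np.exp(ln_flux)
            if system == "grassland":
                for t, val in zip(years, flux):
                    prod_rows.append((site, plot, int(t), s, val))
            else:
                acc = 0.0
                for t, inc in zip(years, flux):
                    acc += inc
                    if truth.mortality_hazard > 0 and rng.random() < truth.mortality_hazard:
                        acc *= 1.0 - rng.uniform(0.2, 0.6)
                    prod_rows.append((site, plot, int(t), s, acc))

    productivity = pd.DataFrame(prod_rows, columns=PRODUCTIVITY_COLUMNS)
    productivity.attrs["kind"] = "biomass" if system == "grassland" else "ba_accumulated"
    composition = pd.DataFrame(comp_rows_all, columns=["site", "plot", "species", "proportion"])
    return productivity, composition
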