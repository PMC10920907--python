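"""Overyielding metrics and the additive biodiversity-effect partition.

Definitions, per mixture plot and year, with O_i the observed
productivity of species i in the mixture, M_i its same-site same-year
monoculture mean, p_i its sown proportion, and E_i = M_i * p_i its
expected productivity:

* species lnRR  = ln(O_i / E_i)             (> 0: the species overyields)
* community lnRR = ln(ΣO_i / ΣE_i)          (> 0: the community overyields)
* additive partition (Loreau & Hector): with ΔRY_i = O_i/M_i − p_i and N
  species, the net effect NE = ΣO − ΣE splits exactly into a
  complementarity effect CE = N·mean(ΔRY)·mean(M) and a selection
  effect SE = N·cov(ΔRY, M) (population covariance).
* PO = fraction of sown species with a positive lnRR, computed for
  overyielding communities only.
* CO_max = (O_imax − E_imax)/(ΣO − ΣE) for the species imax with the
  highest lnRR; per-species contributions (O_i − E_i)/(ΣO − ΣE) sum to 1.

Undefined cases (failed establishment O_i <= 0, dead monoculture
M_i <= 0, ΔY = 0 ...) are never silently dropped: vector functions
return NaN and the table-level driver attaches reason codes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from overyield.io_model import plot_richness

# reason codes for excluded / undefined records
REASON_NONPOS_O = "nonpositive_observed"
REASON_NONPOS_M = "nonpositive_monoculture"
REASON_NO_MONO = "no_monoculture_reference"
REASON_PERCENTILE = "percentile_filter"
REASON_NOT_OVERYIELDING = "community_not_overyielding"
REASON_ZERO_DELTA = "zero_net_deviation"


def species_lnrr(O, M, p):
    """Species log response ratio ln(O / (M p)); NaN where O or M <= 0.

    Positive values mean the species produces more in the mixture than
    expected from its monoculture scaled by its sown proportion.
    """
    O = np.asarray(O, dtype=float)
    M = np.asarray(M, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("species_lnrr is defined for mixtures only: 0 < p < 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where((O > 0) & (M > 0), np.log(O) - np.log(M * p), np.nan)
    return out if out.ndim else float(out)


def community_lnrr(O, M, p):
    """Community log response ratio ln(ΣO / ΣM_i p_i).

    Invariant to how biomass is allocated among species within the
    plot; NaN if ΣO <= 0 or any M_i <= 0 (expected total undefined).
    """
    O = np.asarray(O, dtype=float)
    M = np.asarray(M, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(M <= 0) or O.sum() <= 0:
        return float("nan")
    return float(np.log(O.sum()) - np.log((M * p).sum()))


def partition_additive(O, M, p):
    """Loreau–Hector additive partition -> (NE, CE, SE).

    Uses the population (divide-by-N) covariance so the identity
    NE = CE + SE = ΣO − ΣM_i p_i holds exactly.  NaNs if any M_i <= 0
    (relative yields undefined) or fewer than two species.
    """
    O = np.asarray(O, dtype=float)
    M = np.asarray(M, dtype=float)
    p = np.asarray(p, dtype=float)
    n = len(O)
    if n < 2 or np.any(M <= 0):
        return float("nan"), float("nan"), float("nan")
    dRY = O / M - p
    ce = n * dRY.mean() * M.mean()
    se = n * float(np.mean((dRY - dRY.mean()) * (M - M.mean())))
    return float(ce + se), float(ce), float(se)


def filter_percentile(values, lo: float = 0.005, hi: float = 0.995):
    """Two-tailed percentile filter on a pooled collection of lnRR values.

    Removes entries strictly below the ``lo`` quantile or strictly
    above the ``hi`` quantile of the pooled finite values (linear
    interpolation quantiles).  Intended pooling scope: one system and
    measurement kind across all sites.  Returns
    ``(kept_idx, removed_idx, thresholds)`` as integer positions into
    ``values``.  Fewer than 3 values: nothing is removed.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("filter_percentile expects finite values (drop undefined lnRRs first)")
    idx = np.arange(len(v))
    if len(v) < 3:
        return idx, idx[:0], (float("nan"), float("nan"))
    qlo, qhi = np.quantile(v, [lo, hi])
    removed = (v < qlo) | (v > qhi)
    return idx[~removed], idx[removed], (float(qlo), float(qhi))


def proportion_overyielding(lnrr_values, community_lnrr_value, richness=None):
    """Proportion of overyielding species (PO) and its group label.

    Defined only for overyielding communities (community lnRR > 0).
    The denominator is the sown richness; species whose lnRR is
    undefined (NaN) count as non-overyielding.  Groups: ``lt_half``
    (0 < PO < 0.5), ``ge_half`` (0.5 <= PO < 1), ``all`` (PO = 1).
    """
    v = np.asarray(lnrr_values, dtype=float)
    if not (community_lnrr_value > 0):
        return float("nan"), None
    n = int(richness) if richness is not None else len(v)
    po = float(np.sum(v > 0) / n)
    if po >= 1.0:
        group = "all"
    elif po >= 0.5:
        group = "ge_half"
    elif po > 0:
        group = "lt_half"
    else:
        group = "none"
    return po, group


def co_max(O, M, p, lnrr=None):
    """Contribution of the single highest-lnRR species to ΣO − ΣE.

    ``CO_max = (O_imax − M_imax p_imax) / (ΣO − ΣE)`` where imax is the
    argmax of the species lnRR.  Also returns the full per-species
    contribution vector ``(O_i − E_i)/ΔY`` (sums to 1) and imax.
    CO_max exceeds 1 when the top species' overyielding overcompensates
    underyielding elsewhere.  Ties on lnRR are broken by larger
    absolute deviation |O − E|, then by position (stable order of the
    input, i.e. species id order in table drivers).

    Returns ``(co_max, contributions, imax)``; NaNs if ΔY = 0.
    """
    O = np.asarray(O, dtype=float)
    M = np.asarray(M, dtype=float)
    p = np.asarray(p, dtype=float)
    if lnrr is None:
        lnrr = species_lnrr(O, M, p)
    lnrr = np.asarray(lnrr, dtype=float)
    dev = O - M * p
    dy = dev.sum()
    if dy == 0:
        return float("nan"), np.full_like(dev, np.nan), -1
    finite = np.where(np.isfinite(lnrr), lnrr, -np.inf)
    best = finite.max()
    cand = np.flatnonzero(finite == best)
    imax = int(cand[np.argmax(np.abs(dev[cand]))])
    contributions = dev / dy
    return float(dev[imax] / dy), contributions, imax


def compute_overyielding(
    records: pd.DataFrame,
    composition: pd.DataFrame,
    reference: pd.DataFrame,
    percentile_lo: float = 0.005,
    percentile_hi: float = 0.995,
):
    """Per plot-year overyielding table for all mixture plots.

    Joins observations to sown proportions and monoculture references,
    computes species and community lnRR, the additive partition, PO and
    CO_max, then applies the two-stage exclusion: (1) drop undefined
    species lnRRs with reason codes, (2) two-tailed percentile filter
    (``percentile_lo``/``percentile_hi``) on the pooled finite species
    lnRRs.

    Returns ``(species_table, community_table, summary)``; the species
    table has one row per (site, plot, year, species) with columns
    ``lnrr, contribution, excluded, reason``; the community table one
    row per (site, plot, year) with ``community_lnrr, delta_y, NE, CE,
    SE, PO, PO_group, CO_max, richness``.
    """
    sr = plot_richness(composition)
    mixtures = composition.merge(sr, on=["site", "plot"])
    mixtures = mixtures[mixtures["richness"] > 1]

    df = records.merge(
        mixtures[["site", "plot", "species", "proportion", "richness"]],
        on=["site", "plot", "species"],
        how="inner",
    ).merge(reference, on=["site", "year", "species"], how="left")

    O = df["value"].to_numpy(dtype=float)
    M = df["M"].to_numpy(dtype=float)
    p = df["proportion"].to_numpy(dtype=float)

    reason = np.full(len(df), "", dtype=object)
    reason[~np.isfinite(M)] = REASON_NO_MONO
    reason[(np.isfinite(M)) & (M <= 0)] = REASON_NONPOS_M
    reason[(reason == "") & (O <= 0)] = REASON_NONPOS_O

    lnrr = np.full(len(df), np.nan)
    ok = reason == ""
    with np.errstate(divide="ignore", invalid="ignore"):
        lnrr[ok] = np.log(O[ok]) - np.log(M[ok] * p[ok])

    # stage 2: pooled percentile filter on the finite lnRRs
    finite_idx = np.flatnonzero(np.isfinite(lnrr))
    if len(finite_idx) >= 3:
        _, removed, thresholds = filter_percentile(lnrr[finite_idx], percentile_lo, percentile_hi)
        reason[finite_idx[removed]] = REASON_PERCENTILE
    else:
        thresholds = (float("nan"), float("nan"))

    df["lnrr"] = lnrr
    df["reason"] = reason
    df["excluded"] = reason != ""

    community_rows = []
    contrib = np.full(len(df), np.nan)
    for (site, plot, year), grp in df.groupby(["site", "plot", "year"], sort=True):
        gO = grp["value"].to_numpy(dtype=float)
        gM = grp["M"].to_numpy(dtype=float)
        gp = grp["proportion"].to_numpy(dtype=float)
        richness = int(grp["richness"].iloc[0])
        if np.any(~np.isfinite(gM)) or np.any(gM <= 0):
            community_rows.append(
                dict(site=site, plot=plot, year=year, richness=richness,
                     community_lnrr=np.nan, delta_y=np.nan, NE=np.nan, CE=np.nan,
                     SE=np.nan, PO=np.nan, PO_group=None, CO_max=np.nan,
                     reason=REASON_NONPOS_M if np.any(gM <= 0) else REASON_NO_MONO)
            )
            continue
        clnrr = community_lnrr(gO, gM, gp)
        ne, ce, se = partition_additive(gO, gM, gp)
        dy = float(gO.sum() - (gM * gp).sum())
        glnrr = grp["lnrr"].to_numpy(dtype=float)
        po, group = proportion_overyielding(glnrr, clnrr, richness=richness)
        if dy != 0:
            cmax, contributions, _ = co_max(gO, gM, gp, lnrr=glnrr)
            contrib[grp.index.to_numpy()] = contributions
            reason_c = ""
        else:
            cmax = np.nan
            reason_c = REASON_ZERO_DELTA
        community_rows.append(
            dict(site=site, plot=plot, year=year, richness=richness,
                 community_lnrr=clnrr, delta_y=dy, NE=ne, CE=ce, SE=se,
                 PO=po, PO_group=group, CO_max=cmax, reason=reason_c)
        )

    df["contribution"] = contrib
    species_table = df[
        ["site", "plot", "year", "species", "value", "M", "n_reps", "proportion",
         "richness", "lnrr", "contribution", "excluded", "reason"]
    ].copy()
    community_table = pd.DataFrame(community_rows)
    summary = {
        "n_species_rows": int(len(species_table)),
        "n_plot_years": int(len(community_table)),
        "exclusions": species_table.loc[species_table["excluded"], "reason"]
        .value_counts()
        .to_dict(),
        "percentile_thresholds": {"lo": thresholds[0], "hi": thresholds[1]},
    }
    return species_table, community_table, summary
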