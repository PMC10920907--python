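"""Functional-trait matrix handling: imputation, reliability, strategy axes.

The six traits span the fast–slow plant economics spectrum: specific
leaf area (SLA, mm² mg⁻¹), leaf nitrogen content (LNC, mg g⁻¹), leaf
dry matter content (LDMC, %), specific root length (SRL, m g⁻¹), root
nitrogen content (RNC, mg g⁻¹) and root tissue density (RTD, g cm⁻³).
All trait work happens on the log10 scale; values must be positive.

Missing cells are filled by iterative ensemble-of-trees imputation
(missForest-style: each incomplete trait regressed on all others with
an extremely-randomized-trees forest, iterated to convergence), with
optional phylogenetic eigenvector covariates.  Reliability is assessed
by mask-and-recover NRMSE (RMSE of imputed vs. held-out measured
values divided by the trait's measured range).  Species strategy
scores come from a PCA of the standardized log10 traits, sign-oriented
so that high scores mean acquisitive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.ensemble import ExtraTreesRegressor
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.linear_model import BayesianRidge

TRAITS = ["SLA", "LNC", "LDMC", "SRL", "RNC", "RTD"]

#: high values of these traits mark the acquisitive (fast) end
ACQUISITIVE_TRAITS = ("SLA", "LNC", "SRL", "RNC")
#: high values of these mark the conservative (slow) end
CONSERVATIVE_TRAITS = ("LDMC", "RTD")

#: default per-axis marker traits whose loading is oriented positive
ORIENTATION_MARKERS = {
    "grassland": ("SLA", "LNC"),
    "forest": ("LNC", "SRL"),
}


@dataclass
class StrategyScores:
    """Species scores on the first two strategy axes (high = acquisitive)."""

    scores: pd.DataFrame            # species x [PC1, PC2], unit variance
    loadings: pd.DataFrame          # traits x [PC1, PC2] correlation loadings
    variance_explained: np.ndarray  # fraction per axis, all axes
    flipped_axes: list[str] = field(default_factory=list)


def _validate_trait_frame(matrix: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [t for t in TRAITS if t not in matrix.columns]
    if missing_cols:
        raise ValueError(f"trait matrix lacks column(s) {missing_cols}")
    m = matrix[TRAITS].astype(float)
    if (m <= 0).any().any():
        bad = m.columns[(m <= 0).any()].tolist()
        raise ValueError(f"non-positive trait values in {bad}; traits must be > 0")
    return m


def phylo_eigenvectors(tree, species, n_vectors: int = 10) -> pd.DataFrame:
    """Leading eigenvectors of the double-centred phylogenetic distance matrix.

    A principal-coordinates summary of the phylogeny (patristic
    distances between species), usable as numeric per-species
    covariates in trait imputation.  ``tree`` is a dendropy Tree whose
    taxon labels include every requested species.
    """
    import dendropy

    if not isinstance(tree, dendropy.Tree):
        raise TypeError("tree must be a dendropy.Tree")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    missing = [s for s in species if s not in taxa]
    if missing:
        raise ValueError(f"species absent from phylogeny: {missing[:5]}...")
    n = len(species)
    D = np.zeros((n, n))
    for i, a in enumerate(species):
        for j, b in enumerate(species[i + 1:], start=i + 1):
            D[i, j] = D[j, i] = pdm.patristic_distance(taxa[a], taxa[b])
    # Gower double-centring of -D^2/2, as in principal coordinates
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    w, V = np.linalg.eigh(G)
    order = np.argsort(w)[::-1]
    k = min(n_vectors, np.sum(w[order] > 1e-10))
    vecs = V[:, order[:k]] * np.sqrt(np.maximum(w[order[:k]], 0))
    return pd.DataFrame(vecs, index=pd.Index(species, name="species"),
                        columns=[f"phylo_{i+1}" for i in range(k)])


def _default_imputer(seed, fast: bool = False):
    est = ExtraTreesRegressor(
        n_estimators=30 if fast else 100,
        random_state=np.random.SeedSequence(seed).generate_state(1)[0] % (2**31),
        n_jobs=1,
    )
    return IterativeImputer(estimator=est, max_iter=5 if fast else 10,
                            sample_posterior=False, random_state=seed % (2**31),
                            tol=1e-3)


def _ridge_imputer(seed):
    # documented fallback: iterative regression imputation
    return IterativeImputer(estimator=BayesianRidge(), max_iter=20,
                            random_state=seed % (2**31))


def impute_traits(matrix: pd.DataFrame, phylo_covariates: pd.DataFrame | None = None,
                  seed: int = 0, method: str = "forest", fast: bool = False):
    """Fill missing trait values; returns ``(complete, provenance)``.

    ``matrix`` is species x traits with NaN for missing cells (raw
    units; log10 is applied internally and inverted on output).
    Species with no measured trait at all cannot be anchored and are
    excluded (reported in ``provenance.attrs['excluded_species']``).
    ``provenance`` flags each cell ``measured`` or ``imputed``.
    Deterministic given ``seed``.  ``method``: ``forest`` (iterative
    extra-trees, the default) or ``ridge`` (iterative regression
    fallback).  ``fast`` shrinks the forest for repeated use inside
    cross-validation loops.
    """
    m = matrix[TRAITS].astype(float).copy()
    if (m <= 0).any().any():
        raise ValueError("trait values must be > 0 (log10 transform)")
    measured_any = m.notna().any(axis=1)
    excluded = m.index[~measured_any].tolist()
    m = m[measured_any]

    logm = np.log10(m)
    X = logm.to_numpy()
    if phylo_covariates is not None:
        pc = phylo_covariates.reindex(m.index)
        if pc.isna().any().any():
            raise ValueError("phylo covariates missing for some species")
        X = np.hstack([X, pc.to_numpy(dtype=float)])

    if m.notna().all().all():
        complete = m.copy()
    else:
        imputer = _default_imputer(seed, fast=fast) if method == "forest" else _ridge_imputer(seed)
        with warnings.catch_warnings():
            # tree ensembles rarely hit the imputer's mean-change tolerance;
            # the iteration cap is the intended stopping rule
            warnings.simplefilter("ignore", ConvergenceWarning)
            filled = imputer.fit_transform(X)[:, : len(TRAITS)]
        complete = pd.DataFrame(10.0**filled, index=m.index, columns=TRAITS)
        complete = complete.where(m.isna(), m)  # keep measured cells verbatim

    provenance = pd.DataFrame(
        np.where(m.isna(), "imputed", "measured"), index=m.index, columns=TRAITS
    )
    provenance.attrs["excluded_species"] = excluded
    return complete, provenance


def assess_nrmse(matrix: pd.DataFrame, mask_fraction: float = 0.1, n_repeats: int = 10,
                 seed: int = 0, phylo_covariates: pd.DataFrame | None = None,
                 imputer=None, fast: bool = True) -> pd.DataFrame:
    """Mask-and-recover imputation reliability per trait.

    Each repeat masks ``mask_fraction`` of the *measured* cells at
    random, re-imputes, and scores per-trait
    ``RMSE(true, imputed) / range(measured values)`` — the normalized
    root-mean-square error, on the log10 scale the imputer works on.
    Returns a table with mean NRMSE per trait over repeats and the
    number of evaluated cells; traits with fewer than 5 measured values
    get NaN.  ``imputer`` may override the imputation routine (for
    stubs in testing); it maps ``(masked_matrix, seed)`` -> complete
    DataFrame in raw units.
    """
    if not 0 < mask_fraction <= 0.5:
        raise ValueError("mask_fraction must be in (0, 0.5]")
    m = matrix[TRAITS].astype(float)
    logm = np.log10(m)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA55E55]))

    measured = m.notna()
    counts = measured.sum()
    ranges = logm.max() - logm.min()

    sq_err = {t: [] for t in TRAITS}
    n_cells = {t: 0 for t in TRAITS}
    for rep in range(n_repeats):
        cells = np.argwhere(measured.to_numpy())
        k = max(1, int(round(mask_fraction * len(cells))))
        pick = cells[rng.choice(len(cells), size=k, replace=False)]
        masked = m.copy()
        masked.values[pick[:, 0], pick[:, 1]] = np.nan
        # keep every species anchored by at least one measured trait
        dropped_all = masked.notna().sum(axis=1) == 0
        if dropped_all.any():
            rows = np.flatnonzero(dropped_all.to_numpy())
            pick = pick[~np.isin(pick[:, 0], rows)]
            masked = m.copy()
            masked.values[pick[:, 0], pick[:, 1]] = np.nan
        rep_seed = int(rng.integers(2**31))
        if imputer is not None:
            complete = imputer(masked, rep_seed)
        else:
            complete, _ = impute_traits(masked, phylo_covariates=phylo_covariates,
                                        seed=rep_seed, fast=fast)
        for i, j in pick:
            t = TRAITS[j]
            truth = logm.iat[i, j]
            est = np.log10(complete[t].iloc[i])
            sq_err[t].append((est - truth) ** 2)
            n_cells[t] += 1

    rows = []
    for t in TRAITS:
        if counts[t] < 5 or n_cells[t] == 0:
            rows.append((t, np.nan, int(n_cells[t])))
        else:
            rmse = float(np.sqrt(np.mean(sq_err[t])))
            rows.append((t, rmse / float(ranges[t]), int(n_cells[t])))
    return pd.DataFrame(rows, columns=["trait", "nrmse", "n_cells"]).set_index("trait")


def strategy_axes(matrix: pd.DataFrame, orientation_markers=("SLA", "LNC")) -> StrategyScores:
    """PCA strategy axes from a complete trait matrix.

    Traits are log10-transformed and standardized (zero mean, unit
    variance), i.e. the PCA runs on the trait correlation matrix.  The
    first two axes are kept as species strategy scores, each scaled to
    unit variance and sign-oriented so that its declared acquisitive
    marker trait (``orientation_markers``, one per axis) loads
    positively — high score = acquisitive strategy.
    """
    m = _validate_trait_frame(matrix)
    if m.isna().any().any():
        raise ValueError("strategy_axes needs a complete matrix; impute first")
    logm = np.log10(m.to_numpy())
    sd = logm.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [TRAITS[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant trait column(s): {bad}")
    Z = (logm - logm.mean(axis=0)) / sd

    # PCA via SVD of the standardized matrix
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    if np.sum(s > 1e-12) < 2:
        raise ValueError("trait matrix has rank < 2; cannot extract two axes")
    var = s**2 / np.sum(s**2)
    n = Z.shape[0]
    eigval = s**2 / (n - 1)

    scores = U[:, :2] * np.sqrt(n - 1)          # unit-variance scores
    load = Vt[:2].T * np.sqrt(eigval[:2])       # correlation loadings

    flipped = []
    for k, marker in enumerate(orientation_markers[:2]):
        j = TRAITS.index(marker)
        if load[j, k] < 0:
            load[:, k] *= -1
            scores[:, k] *= -1
            flipped.append(f"PC{k+1}")

    return StrategyScores(
        scores=pd.DataFrame(scores, index=m.index, columns=["PC1", "PC2"]),
        loadings=pd.DataFrame(load, index=TRAITS, columns=["PC1", "PC2"]),
        variance_explained=var,
        flipped_axes=flipped,
    )
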