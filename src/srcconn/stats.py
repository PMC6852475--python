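"""High-dimensional two-group inference with empirical Bayes.

The per-feature statistic is the AUC of the receiver operating
characteristic — the normalised Mann–Whitney U, i.e. the probability that a
random patient value exceeds a random control value (ties count half).
Group labels are permuted to build a feature-wise null, observed and null
AUCs are mapped to a z-scale through the pooled null's empirical CDF, and a
two-group mixture f(z) = pi0 f0(z) + (1 - pi0) f1(z) is fitted: f0 from the
permuted values, f from the observed values, both by Gaussian-kernel
density estimation on a grid.  The local false discovery rate
fdr(z) = pi0 f0(z) / f(z) yields the posterior non-null probability
P1 = 1 - fdr, a discovery mask whose tail-averaged fdr is held at the
requested FDR level, and an estimate of statistical power (share of the
non-null mass captured by the mask).

A key implementation identity: pooled midranks are invariant under label
permutation, so the data are ranked once and every permutation reduces to a
row sum — the permutation null is exact and cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.special import ndtri
from scipy.stats import rankdata
from sklearn.base import BaseEstimator


# ---------------------------------------------------------------------------
# AUC statistic

def auc_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """P(B > A) + 0.5 P(B = A) over all cross-group pairs.

    Values above 0.5 mean group ``b`` is stochastically larger.  Missing
    values are dropped; an empty group yields NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        return np.nan
    ranks = rankdata(np.concatenate([a, b]))
    u = ranks[a.size:].sum() - b.size * (b.size + 1) / 2.0
    return float(u / (a.size * b.size))


def auc_per_feature(values: np.ndarray, is_b: np.ndarray) -> np.ndarray:
    """Column-wise AUC for a subjects x features matrix."""
    is_b = np.asarray(is_b, dtype=bool)
    na, nb = int((~is_b).sum()), int(is_b.sum())
    if na == 0 or nb == 0:
        raise ValueError("both groups must be non-empty")
    if np.isnan(values).any():
        return np.array([auc_statistic(values[~is_b, j], values[is_b, j])
                         for j in range(values.shape[1])])
    ranks = rankdata(values, axis=0)
    u = ranks[is_b].sum(axis=0) - nb * (nb + 1) / 2.0
    return u / (na * nb)


def permutation_null(values: np.ndarray, is_b: np.ndarray, n_perm: int = 500,
                     seed: int = 0) -> np.ndarray:
    """Permuted-label AUCs, shape (n_perm, n_features).

    Ranks are computed once; each permutation is a row-sum over the
    permuted "patient" subset (midranks are label-invariant).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    is_b = np.asarray(is_b, dtype=bool)
    rng = np.random.default_rng(seed)
    n = values.shape[0]
    na, nb = int((~is_b).sum()), int(is_b.sum())
    ranks = rankdata(values, axis=0)
    if np.isnan(values).any():
        # NaNs rank high; drop them feature-wise by masking contributions
        ranks = rankdata(np.where(np.isnan(values), np.nan, values), axis=0,
                         nan_policy="omit")
        ranks = np.nan_to_num(ranks)  # missing subjects contribute rank 0
    sel = np.zeros((n_perm, n), dtype=float)
    for p in range(n_perm):
        sel[p, rng.permutation(n)[:nb]] = 1.0
    u = sel @ ranks - nb * (nb + 1) / 2.0
    return u / (na * nb)


# ---------------------------------------------------------------------------
# empirical Bayes mixture on the z-scale

@dataclass
class EbiResult:
    """Per-feature empirical-Bayes test output."""

    auc: np.ndarray
    z: np.ndarray
    fdr: np.ndarray          # local fdr per feature
    p1: np.ndarray           # posterior non-null probability, 1 - fdr
    pi0: float
    mask: np.ndarray         # significant features at tail-averaged fdr <= q
    threshold: float         # largest local fdr admitted into the mask
    power: float             # share of estimated non-null mass in the mask
    q: float
    grid: np.ndarray
    f0_grid: np.ndarray
    f_grid: np.ndarray


def _null_cdf_z(observed: np.ndarray, null_pool: np.ndarray,
                ) -> tuple[np.ndarray, np.ndarray]:
    """Map observed and null values to z-scores via the pooled null CDF."""
    ns = np.sort(null_pool)
    n = ns.size
    lo = np.searchsorted(ns, observed, side="left")
    hi = np.searchsorted(ns, observed, side="right")
    p_obs = (lo + 0.5 * (hi - lo) + 0.5) / (n + 1.0)
    p_null = (rankdata(null_pool) - 0.5) / n
    return ndtri(p_obs), ndtri(np.clip(p_null, 1e-12, 1 - 1e-12))


def _kde_grid(samples: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Gaussian KDE evaluated on a regular grid via smoothed histogram."""
    n = samples.size
    std = samples.std()
    iqr = np.subtract(*np.percentile(samples, [75, 25]))
    sigma = 0.9 * min(std, iqr / 1.34 if iqr > 0 else std) * n ** (-0.2)
    sigma = max(sigma, 1e-3)
    step = grid[1] - grid[0]
    edges = np.concatenate([grid - step / 2, [grid[-1] + step / 2]])
    hist, _ = np.histogram(samples, bins=edges)
    dens = gaussian_filter1d(hist.astype(float), sigma / step,
                             mode="constant")
    area = np.trapezoid(dens, grid)
    return dens / max(area, 1e-300)


def ebi_fit(observed: np.ndarray, null: np.ndarray, q: float = 0.10,
            n_grid: int = 512, central_halfwidth: float = 1.0) -> EbiResult:
    """Fit the two-group mixture and threshold at FDR ``q``.

    ``null`` may be the (n_perm, n_features) array from
    :func:`permutation_null` or any flat pool of null statistics.
    """
    observed = np.asarray(observed, dtype=float)
    finite = np.isfinite(observed)
    null_pool = np.asarray(null, dtype=float).ravel()
    null_pool = null_pool[np.isfinite(null_pool)]
    if observed[finite].size < 50:
        import warnings
        warnings.warn("fewer than 50 features; density estimates are "
                      "unstable", stacklevel=2)

    z = np.full(observed.size, np.nan)
    z_obs, z_null = _null_cdf_z(observed[finite], null_pool)
    z[finite] = z_obs

    if np.ptp(observed[finite]) == 0:  # degenerate: everything identical
        fdr = np.where(finite, 1.0, np.nan)
        grid = np.linspace(-4, 4, n_grid)
        f0 = _kde_grid(z_null, grid)
        return EbiResult(auc=observed, z=z, fdr=fdr, p1=1 - fdr, pi0=1.0,
                         mask=np.zeros(observed.size, dtype=bool),
                         threshold=0.0, power=0.0, q=q, grid=grid,
                         f0_grid=f0, f_grid=f0)

    span = max(np.abs(z_obs).max(), np.abs(z_null).max()) + 1.0
    grid = np.linspace(-span, span, n_grid)
    f0_grid = _kde_grid(z_null, grid)
    f_grid = _kde_grid(z_obs, grid)

    central = np.abs(grid) <= central_halfwidth
    pi0 = float(np.trapezoid(f_grid[central], grid[central])
                / max(np.trapezoid(f0_grid[central], grid[central]), 1e-300))
    pi0 = min(pi0, 1.0)

    f0_at = np.interp(z[finite], grid, f0_grid)
    f_at = np.maximum(np.interp(z[finite], grid, f_grid), 1e-300)
    fdr = np.full(observed.size, np.nan)
    fdr[finite] = np.minimum(1.0, pi0 * f0_at / f_at)

    # discovery set: largest fdr-ordered prefix with running mean fdr <= q
    order = np.argsort(fdr[finite])
    sorted_fdr = fdr[finite][order]
    running = np.cumsum(sorted_fdr) / np.arange(1, sorted_fdr.size + 1)
    k = int(np.max(np.nonzero(running <= q)[0]) + 1) if np.any(running <= q) else 0
    mask = np.zeros(observed.size, dtype=bool)
    idx_finite = np.nonzero(finite)[0]
    mask[idx_finite[order[:k]]] = True
    threshold = float(sorted_fdr[k - 1]) if k else 0.0

    nonnull_mass = np.nansum(1.0 - fdr)
    power = float(np.nansum((1.0 - fdr)[mask]) / nonnull_mass) \
        if nonnull_mass > 1e-12 else 0.0
    return EbiResult(auc=observed, z=z, fdr=fdr, p1=1 - fdr, pi0=pi0,
                     mask=mask, threshold=threshold, power=power, q=q,
                     grid=grid, f0_grid=f0_grid, f_grid=f_grid)


class EmpiricalBayes(BaseEstimator):
    """Sklearn-style front end for the empirical-Bayes two-group test.

    ``fit(values, groups)`` runs AUC -> permutation null -> mixture fit and
    exposes the fitted quantities as trailing-underscore attributes.
    """

    def __init__(self, q: float = 0.10, n_perm: int = 500, seed: int = 0,
                 n_grid: int = 512, central_halfwidth: float = 1.0):
        self.q = q
        self.n_perm = n_perm
        self.seed = seed
        self.n_grid = n_grid
        self.central_halfwidth = central_halfwidth

    def fit(self, values: np.ndarray, groups: np.ndarray) -> "EmpiricalBayes":
        values = np.asarray(values, dtype=float)
        groups = np.asarray(groups)
        if groups.dtype.kind == "b":
            is_b = groups
        else:
            levels = np.unique(groups)
            if levels.size != 2:
                raise ValueError("exactly two groups required")
            is_b = groups == levels[1]
        self.auc_ = auc_per_feature(values, is_b)
        self.null_ = permutation_null(values, is_b, self.n_perm, self.seed)
        res = ebi_fit(self.auc_, self.null_, q=self.q, n_grid=self.n_grid,
                      central_halfwidth=self.central_halfwidth)
        self.result_ = res
        self.z_ = res.z
        self.fdr_ = res.fdr
        self.p1_ = res.p1
        self.pi0_ = res.pi0
        self.mask_ = res.mask
        self.power_ = res.power
        return self


# ---------------------------------------------------------------------------
# feature pooling

@dataclass
class FeatureMatrix:
    """Subjects x features values plus the feature index and group labels."""

    values: np.ndarray
    index: pd.DataFrame  # quantity, measure, band, roi_i, roi_j, label
    groups: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.groups), len(self.index)):
            raise ValueError("values shape must be subjects x features")
        if len(set(self.groups)) != 2:
            raise ValueError("two non-empty groups required")

    @property
    def is_patient(self) -> np.ndarray:
        # second level in sort order plays the "patient" role
        levels = np.unique(np.asarray(self.groups))
        return np.asarray(self.groups) == levels[1]


def pool_band_power(powers, groups, subject_ids=None) -> FeatureMatrix:
    """Concatenate power across bands: one run over rois x bands features."""
    bands = powers[0].bands
    labels = powers[0].labels
    values = np.stack([p.values.T.ravel() for p in powers])  # band-major
    index = pd.DataFrame([
        {"quantity": "power", "measure": "power", "band": b.name,
         "roi_i": i, "roi_j": -1, "label": labels[i] if labels else str(i)}
        for b in bands for i in range(powers[0].values.shape[0])])
    return FeatureMatrix(values=values, index=index, groups=list(groups),
                         subject_ids=subject_ids or
                         [p.subject for p in powers])


def pool_node_strength(strengths_by_band, groups, measure: str,
                       subject_ids=None) -> FeatureMatrix:
    """Concatenate node strength across bands for one measure.

    ``strengths_by_band``: mapping band name -> list of NodeStrength (one
    per subject, same subject order across bands).
    """
    band_names = list(strengths_by_band)
    cols, rows_index = [], []
    for bn in band_names:
        per_subj = strengths_by_band[bn]
        cols.append(np.stack([s.values for s in per_subj]))
        n_rois = per_subj[0].values.size
        rows_index += [{"quantity": f"{measure}-strength", "measure": measure,
                        "band": bn, "roi_i": i, "roi_j": -1, "label": str(i)}
                       for i in range(n_rois)]
    values = np.concatenate(cols, axis=1)
    sid = subject_ids or [s.subject for s in strengths_by_band[band_names[0]]]
    return FeatureMatrix(values=values, index=pd.DataFrame(rows_index),
                         groups=list(groups), subject_ids=sid)


def edge_features(matrices, groups, subject_ids=None) -> FeatureMatrix:
    """Upper-triangle edge features for one (measure, band) across subjects."""
    m0 = matrices[0]
    iu = np.triu_indices(m0.n_rois, k=1)
    values = np.stack([m.weights[iu] for m in matrices])
    index = pd.DataFrame({
        "quantity": f"{m0.measure}-edge", "measure": m0.measure,
        "band": m0.band.name, "roi_i": iu[0], "roi_j": iu[1],
        "label": [f"{i}-{j}" for i, j in zip(*iu)]})
    return FeatureMatrix(values=values, index=index, groups=list(groups),
                         subject_ids=subject_ids or
                         [m.subject for m in matrices])


# ---------------------------------------------------------------------------
# subgroup ANOVA after inverse-normal transform

def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Blom rank-based transform z = ndtri((r - 0.375) / (n + 0.25))."""
    values = np.asarray(values, dtype=float)
    r = rankdata(values)
    return ndtri((r - 0.375) / (values.size + 0.25))


def subgroup_anova(values, onset, genotype) -> dict[str, float]:
    """Two-way type-II ANOVA (with interaction) on rank-normalised values.

    Returns p-values for the two main effects and their interaction; a
    factor with a single level leaves its effects NaN.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"z": inverse_normal_transform(values),
                       "onset": list(onset), "genotype": list(genotype)})
    cell_counts = df.groupby(["onset", "genotype"]).size()
    if (cell_counts < 2).any():
        raise ValueError("need at least 2 subjects per non-empty cell")
    out = {"onset": np.nan, "genotype": np.nan, "interaction": np.nan}
    if df["onset"].nunique() < 2 or df["genotype"].nunique() < 2:
        single = "onset" if df["onset"].nunique() < 2 else "genotype"
        other = "genotype" if single == "onset" else "onset"
        model = smf.ols(f"z ~ C({other})", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        out[other] = float(table.loc[f"C({other})", "PR(>F)"])
        return out
    model = smf.ols("z ~ C(onset) * C(genotype)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out["onset"] = float(table.loc["C(onset)", "PR(>F)"])
    out["genotype"] = float(table.loc["C(genotype)", "PR(>F)"])
    out["interaction"] = float(table.loc["C(onset):C(genotype)", "PR(>F)"])
    return out


def results_table(fm: FeatureMatrix, res: EbiResult) -> pd.DataFrame:
    """Per-feature results in the documented delimited layout."""
    df = fm.index.copy()
    df["auc"] = res.auc
    df["z"] = res.z
    df["fdr"] = res.fdr
    df["p1"] = res.p1
    df["significant"] = res.mask
    return df
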