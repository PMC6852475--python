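"""Clinical and structural correlates of connectivity read-outs.

Spearman and age-corrected partial Spearman correlations with bootstrap
significance and power, two-stage adaptive FDR, and named-network summary
values (e.g. mean motor-network beta-band iCoh vs ALSFRS-R).

The partial correlation is computed rank-then-residual: all three variables
are midrank-transformed, x and y are each linearly regressed on the ranked
covariate, and the Pearson correlation of the residuals is taken — with no
ties this equals the classical three-rho partial-correlation formula.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .atlas import network_indices
from .containers import ConnectivityMatrix


@dataclass
class SubjectMeta:
    """One row of the subject metadata table; missing fields stay None."""

    subject: str
    group: str
    age: float | None = None
    gender: str | None = None
    onset_site: str | None = None
    genotype: str | None = None
    alsfrs_r: float | None = None
    executive_z: float | None = None
    language_z: float | None = None
    motor_volume: float | None = None
    frontal_volume: float | None = None

    def __post_init__(self) -> None:
        if self.alsfrs_r is not None and not (0 <= self.alsfrs_r <= 48):
            raise ValueError("ALSFRS-R must lie in [0, 48]")


def read_metadata(path) -> list[SubjectMeta]:
    """Load the delimited subject table (documented column names)."""
    df = pd.read_csv(path)
    metas = []
    for _, row in df.iterrows():
        kwargs = {k: (None if pd.isna(v) else v) for k, v in row.items()
                  if k in SubjectMeta.__dataclass_fields__}
        metas.append(SubjectMeta(**kwargs))
    return metas


# ---------------------------------------------------------------------------
# correlations

def _complete(*arrays) -> list[np.ndarray]:
    arrays = [np.asarray(a, dtype=float) for a in arrays]
    keep = np.all([np.isfinite(a) for a in arrays], axis=0)
    return [a[keep] for a in arrays]


def spearman_rho(x, y) -> float:
    """Plain Spearman rank correlation (NaN pairs dropped)."""
    x, y = _complete(x, y)
    if x.size < 5:
        raise ValueError("need at least 5 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    return float(spearmanr(x, y).statistic)


def spearman_partial_rho(x, y, z) -> float:
    """Partial Spearman of x and y controlling for z (rank-then-residual)."""
    x, y, z = _complete(x, y, z)
    if x.size < 6:
        raise ValueError("need at least 6 complete triples")
    if np.ptp(z) == 0:
        warnings.warn("covariate is constant; falling back to plain "
                      "Spearman", stacklevel=2)
        return spearman_rho(x, y)
    rx, ry, rz = rankdata(x), rankdata(y), rankdata(z)
    rz_c = rz - rz.mean()
    ex = rx - rx.mean() - (rx - rx.mean()) @ rz_c / (rz_c @ rz_c) * rz_c
    ey = ry - ry.mean() - (ry - ry.mean()) @ rz_c / (rz_c @ rz_c) * rz_c
    denom = np.linalg.norm(ex) * np.linalg.norm(ey)
    if denom == 0:
        return np.nan
    return float(ex @ ey / denom)


def test_correlation(x, y, z=None, n_boot: int = 2000, seed: int = 0,
                     ) -> tuple[float, float, float]:
    """(rho, p, power) via null permutation and non-null pair bootstrap.

    Null: y permuted ``n_boot`` times; two-sided p with the +1 correction.
    Non-null: pairs resampled with replacement; power = fraction of
    bootstrap |rho| beyond the null's 0.95 two-sided bound.
    """
    if z is None:
        arrays = _complete(x, y)
        estimate = lambda xx, yy: spearman_rho(xx, yy)  # noqa: E731
    else:
        arrays = _complete(x, y, z)
        estimate = lambda xx, yy, zz: spearman_partial_rho(xx, yy, zz)  # noqa: E731
    n = arrays[0].size
    rho = estimate(*arrays)
    rng = np.random.default_rng(seed)
    null = np.empty(n_boot)
    nonnull = np.empty(n_boot)
    for i in range(n_boot):
        perm = rng.permutation(n)
        shuffled = [arrays[0], arrays[1][perm]] + list(arrays[2:])
        null[i] = estimate(*shuffled)
        boot = rng.integers(n, size=n)
        resampled = [a[boot] for a in arrays]
        try:
            nonnull[i] = estimate(*resampled)
        except ValueError:  # degenerate bootstrap draw
            nonnull[i] = np.nan
    p = float((1 + np.sum(np.abs(null) >= abs(rho))) / (n_boot + 1))
    crit = np.quantile(np.abs(null), 0.95)
    power = float(np.nanmean(np.abs(nonnull) > crit))
    return rho, p, power


def spearman(x, y, n_boot: int = 2000, seed: int = 0):
    """(rho, p, power) for the plain Spearman correlation."""
    return test_correlation(x, y, None, n_boot=n_boot, seed=seed)


def spearman_partial(x, y, z, n_boot: int = 2000, seed: int = 0):
    """(rho, p, power) for the age-corrected partial Spearman."""
    return test_correlation(x, y, z, n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# multiple comparisons

def adaptive_fdr(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini–Krieger–Yekutieli two-stage step-up rejection mask.

    First pass: BH step-up at q' = q / (1 + q) estimates the true-null
    count m0 = m - r1; second pass: BH step-up at level q * m / m0.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    q1 = q / (1.0 + q)

    def _bh(pv, level):
        order = np.argsort(pv)
        thresh = level * np.arange(1, m + 1) / m
        passed = pv[order] <= thresh
        k = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
        mask = np.zeros(m, dtype=bool)
        mask[order[:k]] = True
        return mask

    r1 = int(_bh(p, q1).sum())
    if r1 == 0:
        return np.zeros(m, dtype=bool)
    if r1 == m:
        return np.ones(m, dtype=bool)
    m0 = m - r1
    return _bh(p, q1 * m / m0)


# ---------------------------------------------------------------------------
# network summaries

def network_summary(matrix: ConnectivityMatrix,
                    network: str | list[str]) -> float:
    """Mean within-network edge weight for one subject's matrix."""
    idx = network_indices(network, matrix.labels)
    if idx.size < 2:
        raise ValueError("network must contain at least 2 ROIs")
    sub = matrix.weights[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    return float(np.nanmean(sub[iu]))


def correlation_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble CorrelationResult-shaped rows and apply aFDR at 5%."""
    df = pd.DataFrame(rows)
    if not df.empty:
        df["significant"] = adaptive_fdr(df["p"].to_numpy(), q=0.05)
    return df
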