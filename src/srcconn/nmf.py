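"""Ensemble non-negative matrix factorisation of discriminant connectivity.

Edges that separate the groups (two-sided Mann–Whitney, p < .05) are
collected into a non-negative subjects x edges matrix V and decomposed as
V ≈ W·H.  To keep the decomposition balanced and stable the factorisation
is repeated over balanced resamples (all of the smaller group plus an
equal-size random subset of the larger), each solved best-of-restarts with
multiplicative updates; components are aligned across resamples by greedy
cosine matching of H rows before averaging.  Final per-subject weights for
ALL subjects come from non-negative least squares onto the averaged basis.
The rank is chosen by minimising a Gaussian-RSS BIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import mannwhitneyu
from sklearn.base import BaseEstimator

from .containers import ConnectivityMatrix
from .stats import auc_statistic
from .clinical import adaptive_fdr


@dataclass
class EdgeSelection:
    """Group-discriminant edges for one (measure, band) plus their V matrix."""

    measure: str
    band: str
    edges: np.ndarray  # n_edges x 2 ROI indices (upper triangle)
    pvalues: np.ndarray
    v: np.ndarray  # subjects x selected edges, non-negative
    alpha: float


def select_edges(matrices: list[ConnectivityMatrix], groups,
                 alpha: float = 0.05) -> EdgeSelection:
    """Mann–Whitney screen (asymptotic, tie-corrected) at level ``alpha``."""
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size != 2:
        raise ValueError("exactly two groups required")
    is_b = groups == levels[1]
    if min((~is_b).sum(), is_b.sum()) < 10:
        warnings.warn("fewer than 10 subjects in a group; the edge screen "
                      "is underpowered", stacklevel=2)
    m0 = matrices[0]
    iu = np.triu_indices(m0.n_rois, k=1)
    v_full = np.stack([m.weights[iu] for m in matrices])  # subjects x edges
    if alpha <= 0:
        sel = np.zeros(v_full.shape[1], dtype=bool)
        pvals = np.ones(v_full.shape[1])
    else:
        res = mannwhitneyu(v_full[~is_b], v_full[is_b], axis=0,
                           alternative="two-sided", method="asymptotic")
        pvals = np.asarray(res.pvalue)
        sel = pvals < alpha
    edges = np.column_stack([iu[0][sel], iu[1][sel]])
    return EdgeSelection(measure=m0.measure, band=m0.band.name, edges=edges,
                         pvalues=pvals[sel], v=v_full[:, sel], alpha=alpha)


# ---------------------------------------------------------------------------
# core factorisation

def nmf_once(v: np.ndarray, k: int, seed: int = 0, max_iter: int = 500,
             tol: float = 1e-6) -> tuple[np.ndarray, np.ndarray, float, list]:
    """One multiplicative-update NMF run from seeded uniform init.

    Minimises squared Frobenius error; the error sequence is
    non-increasing (the classic multiplicative-update guarantee) and
    iteration stops when its relative change drops below ``tol``.
    Returns (W, H, final error, error trace).
    """
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("V must be non-negative")
    n, m = v.shape
    if k > min(n, m):
        raise ValueError(f"rank {k} exceeds min(V.shape) = {min(n, m)}")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(v.mean(), 1e-12) / k)
    w = rng.uniform(0.1, 1.0, (n, k)) * scale
    h = rng.uniform(0.1, 1.0, (k, m)) * scale
    eps = 1e-12
    trace = []
    err_prev = np.inf
    for _ in range(max_iter):
        h *= (w.T @ v) / (w.T @ w @ h + eps)
        w *= (v @ h.T) / (w @ (h @ h.T) + eps)
        err = float(np.linalg.norm(v - w @ h) ** 2)
        trace.append(err)
        if np.isfinite(err_prev) and err_prev - err <= tol * max(err_prev, eps):
            break
        err_prev = err
    return w, h, trace[-1], trace


def _best_of_restarts(v, k, n_restarts, rng, max_iter, tol):
    best = None
    for _ in range(n_restarts):
        seed = int(rng.integers(2 ** 31))
        w, h, err, _ = nmf_once(v, k, seed=seed, max_iter=max_iter, tol=tol)
        if best is None or err < best[2]:
            best = (w, h, err)
    return best


def select_rank_bic(v: np.ndarray, k_candidates, n_restarts: int = 10,
                    seed: int = 0, max_iter: int = 500, tol: float = 1e-6,
                    ) -> tuple[int, dict[int, float]]:
    """Pick the rank minimising BIC = nm ln(RSS/nm) + k(n+m) ln(nm)."""
    k_candidates = list(k_candidates)
    if not k_candidates:
        raise ValueError("k_candidates must be non-empty")
    rng = np.random.default_rng(seed)
    n, m = v.shape
    trace = {}
    for k in k_candidates:
        _, _, rss, = _best_of_restarts(v, k, n_restarts, rng, max_iter, tol)[:3]
        rss = max(rss, 1e-300)
        trace[k] = n * m * np.log(rss / (n * m)) + k * (n + m) * np.log(n * m)
    best = min(trace, key=trace.get)
    return best, trace


def _greedy_align(h_ref: np.ndarray, h: np.ndarray, w: np.ndarray,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Permute (H, W) components to match a reference basis by cosine sim."""
    k = h_ref.shape[0]
    ref = h_ref / np.maximum(np.linalg.norm(h_ref, axis=1, keepdims=True), 1e-12)
    cur = h / np.maximum(np.linalg.norm(h, axis=1, keepdims=True), 1e-12)
    sim = ref @ cur.T
    perm = np.full(k, -1)
    used = np.zeros(k, dtype=bool)
    for _ in range(k):
        masked = np.where(used[None, :] | (perm != -1)[:, None], -np.inf, sim)
        i, j = np.unravel_index(np.argmax(masked), sim.shape)
        row = np.where(used, -np.inf, sim[i])
        second = np.sort(row)[-2] if k > 1 else -np.inf
        if np.isfinite(second) and sim[i, j] - second < 0.01:
            warnings.warn(f"ambiguous component alignment for module {i} "
                          f"(margin {sim[i, j] - second:.3f})", stacklevel=3)
        perm[i] = j
        used[j] = True
    return h[perm], w[:, perm]


class EnsembleNMF(BaseEstimator):
    """Balanced-resample ensemble NMF with component alignment.

    Parameters
    ----------
    k : int
        Number of modules (pick with :func:`select_rank_bic`).
    n_resamples, n_restarts : int
        Ensemble breadth; desk-scale defaults, both configurable up to the
        protocol scale (250 resamples, 100 restarts).
    seed : int
        Master seed for resampling and restarts.

    Attributes
    ----------
    H_ : ndarray, (k, n_edges)
        Averaged, aligned basis (rows unit-normalised before averaging so
        the arbitrary NMF scale cannot dominate the mean).
    W_ : ndarray, (n_subjects, k)
        Non-negative least-squares weights of every subject on ``H_``.
    """

    def __init__(self, k: int = 2, n_resamples: int = 50,
                 n_restarts: int = 20, seed: int = 0, max_iter: int = 500,
                 tol: float = 1e-6):
        self.k = k
        self.n_resamples = n_resamples
        self.n_restarts = n_restarts
        self.seed = seed
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, v: np.ndarray, groups) -> "EnsembleNMF":
        v = np.asarray(v, dtype=float)
        groups = np.asarray(groups)
        levels = np.unique(groups)
        if levels.size != 2:
            raise ValueError("exactly two groups required")
        idx_a = np.nonzero(groups == levels[0])[0]
        idx_b = np.nonzero(groups == levels[1])[0]
        small, large = (idx_a, idx_b) if idx_a.size <= idx_b.size \
            else (idx_b, idx_a)
        rng = np.random.default_rng(self.seed)

        h_ref = None
        h_sum = np.zeros((self.k, v.shape[1]))
        for _ in range(self.n_resamples):
            sub = rng.choice(large, size=small.size, replace=False)
            rows = np.concatenate([small, sub])
            _, h, _ = _best_of_restarts(v[rows], self.k, self.n_restarts,
                                        rng, self.max_iter, self.tol)
            w_dummy = np.zeros((rows.size, self.k))
            if h_ref is None:
                h_ref = h
            else:
                h, _ = _greedy_align(h_ref, h, w_dummy)
            h_sum += h / np.maximum(
                np.linalg.norm(h, axis=1, keepdims=True), 1e-12)
        self.H_ = h_sum / self.n_resamples
        self.W_ = self.transform(v)
        self.groups_ = groups
        return self

    def transform(self, v: np.ndarray) -> np.ndarray:
        """Project subjects onto the averaged basis (NNLS, non-negative)."""
        if not hasattr(self, "H_"):
            raise RuntimeError("EnsembleNMF is not fitted")
        v = np.asarray(v, dtype=float)
        w = np.empty((v.shape[0], self.H_.shape[0]))
        for s in range(v.shape[0]):
            w[s], _ = nnls(self.H_.T, v[s])
        return w


def ensemble_nmf(v, groups, k, n_resamples=50, n_restarts=20, seed=0,
                 ) -> EnsembleNMF:
    """Functional wrapper over :class:`EnsembleNMF`."""
    return EnsembleNMF(k=k, n_resamples=n_resamples, n_restarts=n_restarts,
                       seed=seed).fit(v, groups)


# ---------------------------------------------------------------------------
# module maps and weight tests

@dataclass
class ModuleMap:
    """Signed, [0, 1]-normalised edge scores of one connectivity module."""

    module: int
    scores: np.ndarray  # per selected edge, min 0 max 1
    sign: int  # +1 increased in patients, -1 decreased
    auc: float
    edges: np.ndarray = field(default=None)  # optional ROI pairs


def module_map(model: EnsembleNMF, groups=None,
               edges: np.ndarray | None = None) -> list[ModuleMap]:
    """Min-max normalise each basis row; sign it by the group AUC of weights."""
    groups = np.asarray(model.groups_ if groups is None else groups)
    levels = np.unique(groups)
    is_b = groups == levels[1]
    maps = []
    for mod in range(model.H_.shape[0]):
        row = model.H_[mod]
        rng_ = row.max() - row.min()
        if rng_ <= 0:
            warnings.warn(f"module {mod} has a constant basis row; dropped",
                          stacklevel=2)
            continue
        scores = (row - row.min()) / rng_
        auc = auc_statistic(model.W_[~is_b, mod], model.W_[is_b, mod])
        sign = 1 if auc >= 0.5 else -1
        maps.append(ModuleMap(module=mod, scores=scores, sign=sign, auc=auc,
                              edges=edges))
    return maps


def test_module_weights(model: EnsembleNMF, groups=None, n_boot: int = 2000,
                        seed: int = 0, q: float = 0.05) -> pd.DataFrame:
    """Permutation p and bootstrap power per module, aFDR-flagged at ``q``.

    Null: group labels permuted (AUC recomputed).  Non-null: within-group
    bootstrap resampling.  Power = share of non-null statistics beyond the
    null's 0.95 quantile of |AUC - 0.5|.
    """
    groups = np.asarray(model.groups_ if groups is None else groups)
    levels = np.unique(groups)
    is_b = groups == levels[1]
    na, nb = int((~is_b).sum()), int(is_b.sum())
    if min(na, nb) < 5:
        raise ValueError("need at least 5 subjects per group")
    rng = np.random.default_rng(seed)
    rows = []
    for mod in range(model.W_.shape[1]):
        wa, wb = model.W_[~is_b, mod], model.W_[is_b, mod]
        obs = auc_statistic(wa, wb)
        pooled = np.concatenate([wa, wb])
        null = np.empty(n_boot)
        nonnull = np.empty(n_boot)
        for i in range(n_boot):
            perm = rng.permutation(pooled)
            null[i] = auc_statistic(perm[:na], perm[na:])
            ra = wa[rng.integers(na, size=na)]
            rb = wb[rng.integers(nb, size=nb)]
            nonnull[i] = auc_statistic(ra, rb)
        dev_null = np.abs(null - 0.5)
        p = (1 + np.sum(dev_null >= abs(obs - 0.5))) / (n_boot + 1)
        crit = np.quantile(dev_null, 0.95)
        power = float(np.mean(np.abs(nonnull - 0.5) > crit))
        rows.append({"module": mod, "auc": obs, "p": p, "power": power})
    df = pd.DataFrame(rows)
    df["significant"] = adaptive_fdr(df["p"].to_numpy(), q=q)
    return df
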