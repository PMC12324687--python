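"""Behavioral partial least squares and dominance analysis.

PLS links two blocks measured on the same subjects — here perfusion maps X
(subjects x locations) and biomarkers Y (subjects x measures). Both blocks
are column z-scored, the cross-block matrix R = X'Y is decomposed by SVD
(R = U S V'), and each singular triplet is one latent variable: U weights
locations, V weights biomarkers, and subject-level scores are XU and YV.
The covariance explained by latent variable k is s_k^2 / sum_j s_j^2.

Inference is resampling-based throughout: latent-variable significance by
permuting the rows of X (singular values compared per ordered component),
weight stability by bootstrap ratios (original weight / bootstrap SE, with
sign alignment per component), and generalizability by repeated 80/20
train-test splits scored by the out-of-sample correlation of the two LV1
scores, against a row-shuffled permutation null.

Dominance analysis decomposes a multiple regression's R^2 across predictors
by exact enumeration of all predictor subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import stream_rng
from .nulls import perm_pvalue

__all__ = [
    "PlsModel",
    "DominanceResult",
    "CrossvalResult",
    "zscore_columns",
    "impute_mode_by_group",
    "pls_fit",
    "pls_permutation",
    "pls_bootstrap",
    "pls_crossval",
    "dominance_analysis",
]


def zscore_columns(a: np.ndarray, mean=None, sd=None) -> np.ndarray:
    """Column z-score (sample sd); optional external statistics for projection."""
    a = np.asarray(a, dtype=float)
    mean = a.mean(axis=0) if mean is None else mean
    sd = a.std(axis=0, ddof=1) if sd is None else sd
    return (a - mean) / sd


def impute_mode_by_group(table: pd.DataFrame, groups: Sequence) -> pd.DataFrame:
    """Fill missing measures with the mode of the measure within each group.

    Mirrors the handling of missing biomarkers: each NaN is replaced by the
    most frequent value of that column among subjects of the same biological
    sex group.
    """
    out = table.copy()
    groups = np.asarray(groups)
    for g in np.unique(groups):
        rows = groups == g
        for col in out.columns:
            block = out.loc[rows, col]
            if block.isna().any():
                mode = block.mode(dropna=True)
                if mode.empty:
                    raise ValueError(f"column {col!r} all-missing in group {g!r}")
                out.loc[rows, col] = block.fillna(mode.iloc[0])
    return out


@dataclass
class PlsModel:
    X: np.ndarray               # column z-scored
    Y: np.ndarray
    U: np.ndarray               # locations x k
    S: np.ndarray
    V: np.ndarray               # measures x k
    brain_scores: np.ndarray    # XU
    biomarker_scores: np.ndarray  # YV
    x_loadings: np.ndarray      # corr(X column, brain score), per component
    y_loadings: np.ndarray
    covariance_explained: np.ndarray


def _colcorr(block: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """corr of every column of block with every score column."""
    bz = block - block.mean(axis=0)
    sz = scores - scores.mean(axis=0)
    denom = np.sqrt(np.outer((bz ** 2).sum(axis=0), (sz ** 2).sum(axis=0)))
    return (bz.T @ sz) / denom


def pls_fit(X_raw: np.ndarray, Y_raw: np.ndarray,
            n_components: Optional[int] = None) -> PlsModel:
    """Fit behavioral PLS: z-score columns, SVD of X'Y, scores and loadings."""
    X_raw = np.asarray(X_raw, dtype=float)
    Y_raw = np.asarray(Y_raw, dtype=float)
    if X_raw.shape[0] != Y_raw.shape[0]:
        raise ValueError("X and Y must have the same number of subjects")
    if X_raw.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    for name, block in (("X", X_raw), ("Y", Y_raw)):
        sd = block.std(axis=0, ddof=1)
        bad = np.where(sd == 0)[0]
        if bad.size:
            raise ValueError(f"constant column(s) in {name}: {bad[:5].tolist()}")
    X = zscore_columns(X_raw)
    Y = zscore_columns(Y_raw)
    r = X.T @ Y
    u, s, vt = np.linalg.svd(r, full_matrices=False)
    k = len(s) if n_components is None else int(n_components)
    if k > len(s):
        raise ValueError("n_components exceeds the number of singular triplets")
    cov_explained = s ** 2 / np.sum(s ** 2)
    u, vt = u[:, :k], vt[:k]
    brain = X @ u
    bio = Y @ vt.T
    return PlsModel(X=X, Y=Y, U=u, S=s[:k], V=vt.T,
                    brain_scores=brain, biomarker_scores=bio,
                    x_loadings=_colcorr(X, brain), y_loadings=_colcorr(Y, bio),
                    covariance_explained=cov_explained[:k])


def pls_permutation(model: PlsModel, n_perm: int = 1000, seed: int = 0,
                    shuffle: str = "x") -> np.ndarray:
    """Permutation p per latent variable: shuffle rows, re-SVD, compare s_k in order.

    ``shuffle='x'`` permutes the rows of X (``'y'`` is the distributionally
    equivalent alternative). Inclusive one-sided p-values.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if shuffle not in ("x", "y"):
        raise ValueError("shuffle must be 'x' or 'y'")
    k = len(model.S)
    null_s = np.empty((n_perm, k))
    n = model.X.shape[0]
    for p in range(n_perm):
        rng = stream_rng(seed, p)
        perm = rng.permutation(n)
        if shuffle == "x":
            r = model.X[perm].T @ model.Y
        else:
            r = model.X.T @ model.Y[perm]
        s = np.linalg.svd(r, compute_uv=False)
        null_s[p] = s[:k]
    return np.array([perm_pvalue(model.S[j], null_s[:, j], "greater")
                     for j in range(k)])


def pls_bootstrap(model: PlsModel, n_boot: int = 1000, seed: int = 0,
                  _resampler=None) -> dict:
    """Bootstrap ratios for biomarker (and location) weights.

    Subjects are resampled with replacement, both blocks re-z-scored and
    re-decomposed; resampled singular vectors are sign-aligned to the
    original by the sign of their inner product, and the bootstrap ratio is
    original weight / bootstrap sd of that weight. A zero bootstrap sd
    yields a signed-infinity sentinel with a warning.
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    n, k = model.X.shape[0], len(model.S)
    u_samples = np.empty((n_boot, model.U.shape[0], k))
    v_samples = np.empty((n_boot, model.V.shape[0], k))
    for b in range(n_boot):
        rng = stream_rng(seed, b)
        idx = rng.integers(0, n, size=n) if _resampler is None else _resampler(rng, n)
        xb, yb = model.X[idx], model.Y[idx]
        sdx = xb.std(axis=0, ddof=1)
        sdy = yb.std(axis=0, ddof=1)
        sdx[sdx == 0] = 1.0  # degenerate resample of a column: leave centered only
        sdy[sdy == 0] = 1.0
        xb = (xb - xb.mean(axis=0)) / sdx
        yb = (yb - yb.mean(axis=0)) / sdy
        ub, sb, vbt = np.linalg.svd(xb.T @ yb, full_matrices=False)
        ub, vb = ub[:, :k], vbt[:k].T
        signs = np.sign(np.sum(vb * model.V, axis=0))
        signs[signs == 0] = 1.0
        u_samples[b] = ub * signs
        v_samples[b] = vb * signs
    u_sd = u_samples.std(axis=0, ddof=1)
    v_sd = v_samples.std(axis=0, ddof=1)
    if np.any(u_sd == 0) or np.any(v_sd == 0):
        warnings.warn("zero bootstrap sd for some weights; reporting signed infinity",
                      RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        u_ratio = np.where(u_sd > 0, model.U / np.where(u_sd > 0, u_sd, 1.0),
                           np.sign(model.U) * np.inf)
        v_ratio = np.where(v_sd > 0, model.V / np.where(v_sd > 0, v_sd, 1.0),
                           np.sign(model.V) * np.inf)
    return {"x_bootstrap_ratios": u_ratio, "y_bootstrap_ratios": v_ratio,
            "u_sd": u_sd, "v_sd": v_sd}


@dataclass
class CrossvalResult:
    mean_r: float
    split_r: np.ndarray
    null_mean_r: np.ndarray
    p: float


def pls_crossval(X_raw: np.ndarray, Y_raw: np.ndarray,
                 train_fraction: float = 0.8, n_splits: int = 1000,
                 n_perm: int = 1000, seed: int = 0,
                 n_splits_null: int = 20) -> CrossvalResult:
    """Out-of-sample LV1 score correlation over random train/test splits.

    Per split, the PLS weights are estimated on the training subjects
    (column statistics from the training block only) and the held-out
    subjects are projected (X_test U_train, Y_test V_train); the recorded
    statistic is the Pearson correlation of the two test-score vectors. The
    permutation null shuffles X rows before splitting and records the mean
    correlation over ``n_splits_null`` splits per permutation; the p-value
    compares the observed mean against that null, inclusively.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    X_raw = np.asarray(X_raw, dtype=float)
    Y_raw = np.asarray(Y_raw, dtype=float)
    n = X_raw.shape[0]
    n_train = int(round(train_fraction * n))
    if n - n_train < 3:
        raise ValueError("test split needs at least 3 subjects")
    reference = pls_fit(X_raw, Y_raw, n_components=1)

    def one_split(xr, yr, rng):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        mx, sx = xr[tr].mean(axis=0), xr[tr].std(axis=0, ddof=1)
        my, sy = yr[tr].mean(axis=0), yr[tr].std(axis=0, ddof=1)
        sx[sx == 0] = 1.0
        sy[sy == 0] = 1.0
        xt = (xr[tr] - mx) / sx
        yt = (yr[tr] - my) / sy
        u, s, vt = np.linalg.svd(xt.T @ yt, full_matrices=False)
        u1, v1 = u[:, 0], vt[0]
        # align the training weights to the full-sample model so the split
        # correlations do not flip sign with the SVD's sign ambiguity
        if u1 @ reference.U[:, 0] < 0:
            u1, v1 = -u1, -v1
        bs = ((xr[te] - mx) / sx) @ u1
        ys = ((yr[te] - my) / sy) @ v1
        if bs.std() == 0 or ys.std() == 0:
            return 0.0
        return float(np.corrcoef(bs, ys)[0, 1])

    split_r = np.array([one_split(X_raw, Y_raw, stream_rng(seed, s))
                        for s in range(n_splits)])
    mean_r = float(split_r.mean())

    null_means = np.empty(n_perm)
    for p in range(n_perm):
        rng = stream_rng(seed, 10_000_019 + p)
        xp = X_raw[rng.permutation(n)]
        rs = [one_split(xp, Y_raw, stream_rng(seed, 20_000_033 + p * n_splits_null + s))
              for s in range(n_splits_null)]
        null_means[p] = np.mean(rs)
    pval = perm_pvalue(mean_r, null_means, "greater")
    return CrossvalResult(mean_r=mean_r, split_r=split_r,
                          null_mean_r=null_means, p=pval)


@dataclass
class DominanceResult:
    total_r2: float
    contributions: np.ndarray
    percent: np.ndarray


def _subset_r2(X: np.ndarray, y: np.ndarray) -> float:
    design = np.column_stack([np.ones(len(y)), X]) if X.shape[1] else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = np.sum((y - y.mean()) ** 2)
    return float(1.0 - np.sum(resid ** 2) / tss)


def dominance_analysis(X: np.ndarray, y: np.ndarray) -> DominanceResult:
    """Total dominance decomposition of regression R^2 by subset enumeration.

    For each predictor, the incremental R^2 of adding it is averaged over
    all subsets of the other predictors within each subset size, then
    averaged across sizes; the contributions sum to the full-model R^2.
    Limited to 20 predictors (2^p subsets are enumerated exactly).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    if p > 20:
        raise ValueError("more than 20 predictors; select a subset first")
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X])) < p + 1:
        raise ValueError("rank-deficient predictor matrix")
    r2 = {}
    idx = tuple(range(p))
    for size in range(p + 1):
        for sub in combinations(idx, size):
            r2[sub] = _subset_r2(X[:, sub], y)
    contributions = np.zeros(p)
    for i in range(p):
        others = tuple(j for j in idx if j != i)
        level_means = []
        for size in range(p):
            incs = [r2[tuple(sorted(sub + (i,)))] - r2[sub]
                    for sub in combinations(others, size)]
            level_means.append(np.mean(incs))
        contributions[i] = np.mean(level_means)
    total = r2[idx]
    if np.any(contributions < -1e-10):
        warnings.warn("negative dominance contributions: ill-posed design",
                      RuntimeWarning, stacklevel=2)
    percent = 100.0 * contributions / total if total > 0 else np.zeros(p)
    return DominanceResult(total_r2=total, contributions=contributions, percent=percent)
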