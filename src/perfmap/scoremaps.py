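"""Score maps, per-location GLM effect maps, residualization, and contrasts.

The entry point of the group analyses is a subjects x locations matrix of
perfusion values with per-subject age and sex (coded male = 1, female = 0).
Subject maps are z-scored within subject, concatenated, and summarised by
the first principal component ("perfusion score map"); age and sex effects
are mapped with per-location ordinary least squares; and group contrasts of
effect maps (e.g. unimodal vs transmodal age slopes) are tested with both
Welch t and spatial-null permutation p-values.

z-scoring uses the sample standard deviation (divisor n - 1) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scistats

from .nulls import NullEnsemble, apply_ensemble, perm_pvalue

__all__ = [
    "ScoreMapResult",
    "GlmResult",
    "ContrastResult",
    "standardize_subjects",
    "pca_score_map",
    "build_design",
    "glm_effect_maps",
    "residualize_covariates",
    "strength_map",
    "network_contrast",
    "RESIDUAL_TERMS",
]

#: cubic age polynomial with full sex interactions (the covariate-regression design)
RESIDUAL_TERMS = ("age", "sex", "sex:age", "age^2", "sex:age^2", "age^3", "sex:age^3")


def standardize_subjects(values: np.ndarray) -> np.ndarray:
    """z-score each subject's map (row mean 0, sample sd 1)."""
    values = np.asarray(values, dtype=float)
    sd = values.std(axis=1, ddof=1)
    bad = np.where(sd == 0)[0]
    if bad.size:
        raise ValueError(f"constant map for subject(s) {bad[:5].tolist()}")
    return (values - values.mean(axis=1, keepdims=True)) / sd[:, None]


@dataclass
class ScoreMapResult:
    """First-component spatial pattern with per-subject loadings."""

    score_map: np.ndarray
    subject_loadings: np.ndarray
    variance_explained: np.ndarray
    components: np.ndarray  # n_components x locations


def pca_score_map(values: np.ndarray, n_components: int = 1,
                  center_columns: bool = False) -> ScoreMapResult:
    """PCA of the stacked subject maps via SVD.

    By default columns are *not* centered, so the first component can absorb
    the shared mean pattern (the score map then closely tracks the group
    mean map); ``center_columns=True`` gives the textbook variant. The score
    map sign is fixed so its correlation with the column mean map is
    non-negative. ``variance_explained_k`` = s_k^2 / sum_j s_j^2.
    """
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if n_components > min(n, p):
        raise ValueError("n_components exceeds matrix rank bound")
    mean_map = values.mean(axis=0)
    work = values - mean_map[None, :] if center_columns else values
    u, s, vt = np.linalg.svd(work, full_matrices=False)
    var_explained = s ** 2 / np.sum(s ** 2)
    score_map = vt[0]
    loadings = u[:, 0] * s[0]
    ref = mean_map - mean_map.mean()
    if score_map @ ref < 0:
        score_map = -score_map
        loadings = -loadings
        vt = vt.copy()
        vt[0] = score_map
    return ScoreMapResult(score_map=score_map, subject_loadings=loadings,
                          variance_explained=var_explained[:n_components],
                          components=vt[:n_components])


def _term_column(term: str, age: np.ndarray, sex: np.ndarray) -> np.ndarray:
    parts = term.split(":")
    col = np.ones_like(age)
    for p in parts:
        if p == "sex":
            col = col * sex
        elif p == "age":
            col = col * age
        elif p.startswith("age^"):
            col = col * age ** int(p.split("^")[1])
        else:
            raise ValueError(f"unknown design term {term!r}")
    return col


def build_design(covariates: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    """Design matrix [intercept | terms] from age/sex covariates."""
    age = covariates["age"].to_numpy(dtype=float)
    sex = covariates["sex"].to_numpy(dtype=float)
    cols = [np.ones_like(age)] + [_term_column(t, age, sex) for t in terms]
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        # report which added terms are collinear with the preceding ones
        collinear = []
        for j in range(1, design.shape[1]):
            if np.linalg.matrix_rank(design[:, :j + 1]) < j + 1:
                collinear.append(terms[j - 1])
        raise ValueError(f"rank-deficient design; collinear terms: {collinear}")
    return design


@dataclass
class GlmResult:
    """Per-location OLS coefficients, standard errors, p-values and a Bonferroni mask."""

    terms: tuple
    coefficients: np.ndarray   # (1 + n_terms) x n_locations, row 0 = intercept
    standard_errors: np.ndarray
    p_values: np.ndarray       # two-sided t-based
    bonferroni_mask: np.ndarray  # same shape; p < 0.05 / n_locations
    residuals: np.ndarray

    def coef(self, term: str) -> np.ndarray:
        names = ("intercept",) + self.terms
        return self.coefficients[names.index(term)]


def glm_effect_maps(values: np.ndarray, covariates: pd.DataFrame,
                    terms: Sequence[str] = ("age", "sex"),
                    alpha: float = 0.05) -> GlmResult:
    """Per-location ordinary least squares effect maps.

    The same design (intercept + terms) is fitted to every location; p-values
    are two-sided t, and the Bonferroni mask thresholds at alpha divided by
    the number of locations.
    """
    values = np.asarray(values, dtype=float)
    design = build_design(covariates, terms)
    n, k = design.shape
    if n <= k:
        raise ValueError("more design columns than subjects")
    # QR keeps the cubic-age designs well conditioned (normal equations
    # square the condition number)
    q, r = np.linalg.qr(design)
    coefs = np.linalg.solve(r, q.T @ values)     # k x n_locations
    r_inv = np.linalg.solve(r, np.eye(k))
    xtx_inv = r_inv @ r_inv.T
    resid = values - design @ coefs
    dof = n - k
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = coefs / se
    pvals = 2.0 * _scistats.t.sf(np.abs(tvals), dof)
    mask = pvals < alpha / values.shape[1]
    return GlmResult(terms=tuple(terms), coefficients=coefs, standard_errors=se,
                     p_values=pvals, bonferroni_mask=mask, residuals=resid)


def residualize_covariates(values: np.ndarray, covariates: pd.DataFrame,
                           terms: Sequence[str] = RESIDUAL_TERMS,
                           keep_intercept: bool = False) -> np.ndarray:
    """Residuals of every location after regressing out the covariate design.

    The default design is the cubic age polynomial with sex and all
    sex-by-age interactions. With ``keep_intercept=False`` the result is the
    raw residual (observed - fitted), orthogonal to every design column
    including the constant; ``keep_intercept=True`` adds each location's
    intercept back, giving covariate-adjusted maps that retain the group
    mean pattern (the variant used when a score map is recomputed after
    covariate adjustment).
    """
    fit = glm_effect_maps(values, covariates, terms)
    if keep_intercept:
        return fit.residuals + fit.coef("intercept")[None, :]
    return fit.residuals


def strength_map(connectivity: np.ndarray) -> np.ndarray:
    """Node strength: sum of absolute edge weights per region, diagonal excluded."""
    w = np.asarray(connectivity, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("connectivity must be square")
    a = np.abs(w).copy()
    np.fill_diagonal(a, 0.0)
    return a.sum(axis=1)


@dataclass
class ContrastResult:
    """Group mean difference of a map with parametric and spatial-null p-values."""

    delta: float
    t: float
    p_parametric: float
    p_spin: float
    null_deltas: np.ndarray


def network_contrast(map_values: np.ndarray, labels: np.ndarray,
                     ensemble: NullEnsemble, side: str = "two-sided") -> ContrastResult:
    """Contrast a map between two location groups (e.g. unimodal vs transmodal).

    delta = mean(group 1) - mean(group 0); the parametric test is Welch's t;
    the spatial-null p recomputes delta with the map's values spun over
    locations while the labels stay fixed.
    """
    map_values = np.asarray(map_values, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary (0/1)")
    a = map_values[labels == 1]
    b = map_values[labels == 0]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    delta = float(a.mean() - b.mean())
    if a.size > 1 and b.size > 1 and (a.std() > 0 or b.std() > 0):
        t, p_par = _scistats.ttest_ind(a, b, equal_var=False)
    elif delta == 0:
        t, p_par = 0.0, 1.0
    else:  # constant groups with different means: infinitely separated
        t, p_par = np.sign(delta) * np.inf, 0.0
    null_maps = apply_ensemble(ensemble, map_values)
    null_delta = (null_maps[:, labels == 1].mean(axis=1)
                  - null_maps[:, labels == 0].mean(axis=1))
    if side == "two-sided":
        p_spin = perm_pvalue(delta, null_delta, "two-sided")
    else:
        p_spin = perm_pvalue(delta, null_delta, side)
    return ContrastResult(delta=delta, t=float(t), p_parametric=float(p_par),
                          p_spin=p_spin, null_deltas=null_delta)
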