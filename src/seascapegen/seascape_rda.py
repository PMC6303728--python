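"""Distance-based redundancy analysis (dbRDA) of genetic differentiation on
environmental, geographic (PCNM), and larval-recruitment predictors.

The response is a symmetric dissimilarity matrix over sites (here typically a
pairwise FST matrix).  It is Gower double-centered, eigen-decomposed, and the
positive-eigenvalue site coordinates are regressed on standardized predictors
(capscale-style).  Permutation F-tests, forward selection, and adjusted-R²
variance partitioning follow the vegan conventions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree

__all__ = [
    "PredictorTable",
    "DbRdaModel",
    "VarPartResult",
    "pcnm_axes",
    "dbrda_fit",
    "forward_select",
    "marginal_permutation_anova",
    "variance_partition",
    "pearson_screen",
]


@dataclass
class PredictorTable:
    """Site-aligned predictor columns, standardized to zero mean / unit variance."""

    data: pd.DataFrame  # index = site labels
    standardized: bool = False

    def __post_init__(self):
        if self.data.isna().any().any():
            raise ValueError("predictor table contains missing cells")

    def standardize(self) -> "PredictorTable":
        if self.standardized:
            return self
        sd = self.data.std(ddof=1)
        if (sd == 0).any():
            bad = list(sd.index[sd == 0])
            raise ValueError(f"constant predictor column(s): {bad}")
        z = (self.data - self.data.mean()) / sd
        return PredictorTable(data=z, standardized=True)


@dataclass
class DbRdaModel:
    response: np.ndarray  # the dissimilarity matrix
    predictors: pd.DataFrame  # standardized design columns actually used
    constrained_eigenvalues: np.ndarray
    unconstrained_eigenvalues: np.ndarray
    negative_eigenvalues: np.ndarray
    site_scores: np.ndarray  # sites x constrained axes
    biplot_scores: pd.DataFrame  # predictor x constrained axes correlations
    total_inertia: float
    constrained_inertia: float

    @property
    def residual_inertia(self) -> float:
        return self.total_inertia - self.constrained_inertia

    @property
    def constrained_proportion(self) -> float:
        return self.constrained_inertia / self.total_inertia


@dataclass
class VarPartResult:
    set_names: list
    unique: dict  # set name -> unique adjusted-R² fraction
    shared: dict  # frozenset of >=2 names -> shared fraction
    residual: float
    r2_adj_full: float


# ---------------------------------------------------------------------------
# PCNM spatial eigenvectors


def pcnm_axes(
    coords: np.ndarray | dict | None = None,
    dist: np.ndarray | None = None,
    eps: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates of neighbour matrices (Moran eigenvector maps).

    The distance matrix is truncated at the longest edge of its minimum
    spanning tree; larger distances are replaced by 4x the threshold; the
    truncated matrix is double-centered and eigen-decomposed.  Returns
    (axes, eigenvalues) for the positive-eigenvalue axes (columns orthogonal).
    """
    if dist is None:
        if coords is None:
            raise ValueError("need coords or a distance matrix")
        if isinstance(coords, dict):
            coords = np.array(list(coords.values()), dtype=float)
        coords = np.asarray(coords, dtype=float)
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=-1))
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if n < 3:
        raise ValueError("need >= 3 sites")
    if np.all(dist == 0):
        raise ValueError("all sites coincident")

    mst = minimum_spanning_tree(dist).toarray()
    threshold = mst.max()
    d = dist.copy()
    d[d > threshold] = 4.0 * threshold

    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (d**2) @ J
    w, V = np.linalg.eigh(G)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    pos = w > eps * max(abs(w[0]), 1.0)
    return V[:, pos], w[pos]


# ---------------------------------------------------------------------------
# dbRDA core


def _gower_center(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ (D**2) @ J


def _pcoa_axes(D: np.ndarray, eps: float = 1e-9):
    """Positive-axis PCoA coordinates Y (n x k, Y @ Y.T ≈ G) + eigenvalues."""
    G = _gower_center(D)
    G = 0.5 * (G + G.T)
    w, V = np.linalg.eigh(G)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    scale = max(abs(w[0]), 1.0)
    pos = w > eps * scale
    neg = w < -eps * scale
    Y = V[:, pos] * np.sqrt(w[pos])
    return Y, w[pos], w[neg]


def _design_matrix(predictors) -> pd.DataFrame:
    if isinstance(predictors, PredictorTable):
        return predictors.standardize().data
    X = pd.DataFrame(predictors).astype(float)
    sd = X.std(ddof=1)
    if (sd == 0).any():
        raise ValueError(f"constant predictor column(s): {list(sd.index[sd == 0])}")
    return (X - X.mean()) / sd


def _hat(X: np.ndarray) -> np.ndarray:
    # column-centered X (intercept implicit through centering of both sides)
    Q, R = np.linalg.qr(X)
    keep = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(np.diag(R)).max())
    Q = Q[:, keep]
    return Q @ Q.T


def dbrda_fit(response: np.ndarray, predictors, check_rank: bool = True) -> DbRdaModel:
    """Fit a distance-based RDA (vegan capscale equivalent).

    ``response`` is a symmetric dissimilarity matrix with a zero diagonal,
    row-aligned with the predictor table.  Negative-eigenvalue PCoA axes are
    excluded from the regression and reported separately.
    """
    D = np.asarray(response, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("response must be a square matrix")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("response must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("response must have a zero diagonal")
    X = _design_matrix(predictors)
    n = D.shape[0]
    if len(X) != n:
        raise ValueError("predictor rows must align with the response matrix")
    if n <= X.shape[1] + 1:
        raise ValueError("need n_sites > n_predictors + 1")
    if check_rank:
        r = np.linalg.matrix_rank(X.values - X.values.mean(axis=0))
        if r < X.shape[1]:
            raise ValueError("rank-deficient (collinear) predictor columns")

    Y, pos_eig, neg_eig = _pcoa_axes(D)
    total_inertia = float(pos_eig.sum())

    H = _hat(X.values - X.values.mean(axis=0))
    Yhat = H @ Y
    # constrained axes: eigen-analysis of the fitted values
    C = Yhat.T @ Yhat
    w, V = np.linalg.eigh(0.5 * (C + C.T))
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    keep = w > 1e-12 * max(abs(w[0]), 1.0) if w.size else np.zeros(0, dtype=bool)
    cons_eig = w[keep]
    site_scores = Yhat @ V[:, keep]

    Yres = Y - Yhat
    Cr = Yres.T @ Yres
    wr = np.linalg.eigvalsh(0.5 * (Cr + Cr.T))[::-1]
    unc_eig = wr[wr > 1e-12 * max(abs(wr[0]), 1.0)] if wr.size else wr

    if site_scores.shape[1] and X.shape[1]:
        bip = np.zeros((X.shape[1], site_scores.shape[1]))
        for j in range(X.shape[1]):
            for k in range(site_scores.shape[1]):
                sx = np.std(X.values[:, j])
                sy = np.std(site_scores[:, k])
                bip[j, k] = (
                    0.0 if sx == 0 or sy == 0
                    else np.corrcoef(X.values[:, j], site_scores[:, k])[0, 1]
                )
        biplot = pd.DataFrame(
            bip, index=X.columns,
            columns=[f"dbRDA{k+1}" for k in range(site_scores.shape[1])],
        )
    else:
        biplot = pd.DataFrame(index=X.columns)

    return DbRdaModel(
        response=D,
        predictors=X,
        constrained_eigenvalues=cons_eig,
        unconstrained_eigenvalues=unc_eig,
        negative_eigenvalues=neg_eig,
        site_scores=site_scores,
        biplot_scores=biplot,
        total_inertia=total_inertia,
        constrained_inertia=float(cons_eig.sum()),
    )


def _inertia_explained(Y: np.ndarray, X: np.ndarray) -> float:
    H = _hat(X - X.mean(axis=0))
    Yhat = H @ Y
    return float(np.sum(Yhat * Yhat))


def _perm_f_test(
    Y: np.ndarray,
    X_full: np.ndarray,
    X_reduced: np.ndarray | None,
    df_term: int,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Permutation F-test for the terms in X_full beyond X_reduced.

    Residuals of the reduced model are permuted (rows) and added back to the
    reduced fit; F compares the added constrained inertia per df to the
    residual inertia of the full model per df.
    """
    n = Y.shape[0]
    total = float(np.sum(Y * Y))
    full = _inertia_explained(Y, X_full)
    m_full = np.linalg.matrix_rank(X_full - X_full.mean(axis=0))
    df_res = n - 1 - m_full
    if df_res <= 0:
        raise ValueError("zero residual degrees of freedom")
    if X_reduced is None or X_reduced.shape[1] == 0:
        reduced = 0.0
        Yfit_red = np.zeros_like(Y)
        Yres_red = Y
    else:
        H_red = _hat(X_reduced - X_reduced.mean(axis=0))
        Yfit_red = H_red @ Y
        Yres_red = Y - Yfit_red
        reduced = float(np.sum(Yfit_red * Yfit_red))
    added = full - reduced
    F_obs = (added / df_term) / ((total - full) / df_res)

    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Yp = Yfit_red + Yres_red[perm]
        totp = float(np.sum(Yp * Yp))
        fullp = _inertia_explained(Yp, X_full)
        if X_reduced is None or X_reduced.shape[1] == 0:
            redp = 0.0
        else:
            redp = float(np.sum((_hat(X_reduced - X_reduced.mean(axis=0)) @ Yp) ** 2))
        Fp = ((fullp - redp) / df_term) / ((totp - fullp) / df_res)
        if Fp >= F_obs - 1e-12:
            count += 1
    return F_obs, (count + 1) / (n_perm + 1)


def marginal_permutation_anova(
    model: DbRdaModel, n_perm: int = 999, seed: int = 0
) -> pd.DataFrame:
    """Marginal (type-III-style) permutation tests: each term after all others.

    Returns a tidy frame (term, df, F, p).  The null for each term permutes
    residuals of the model containing every other term.
    """
    X = model.predictors
    if X.shape[1] == 0:
        raise ValueError("model has no terms")
    Y, _, _ = _pcoa_axes(model.response)
    rng = np.random.default_rng(seed)
    rows = []
    for term in X.columns:
        others = [c for c in X.columns if c != term]
        Xr = X[others].values if others else None
        F, p = _perm_f_test(Y, X.values, Xr, 1, n_perm, rng)
        rows.append({"term": term, "df": 1, "F": F, "p": p})
    return pd.DataFrame(rows)


def global_permutation_test(
    response: np.ndarray, predictors, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Overall model significance against the intercept-only null."""
    X = _design_matrix(predictors)
    Y, _, _ = _pcoa_axes(np.asarray(response, dtype=float))
    rng = np.random.default_rng(seed)
    m = X.shape[1]
    return _perm_f_test(Y, X.values, None, m, n_perm, rng)


def forward_select(
    response: np.ndarray,
    candidate_predictors,
    alpha_add: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
) -> list:
    """Forward selection of predictors by marginal permutation p-value.

    At each step the candidate with the lowest p for its contribution given the
    current model is added if p < alpha_add (ties broken by larger F); the
    procedure stops when no candidate qualifies.
    """
    X_all = _design_matrix(candidate_predictors)
    if X_all.shape[1] < 2:
        raise ValueError("need >= 2 candidates")
    D = np.asarray(response, dtype=float)
    Y, _, _ = _pcoa_axes(D)
    rng = np.random.default_rng(seed)
    selected: list = []
    remaining = list(X_all.columns)
    n = Y.shape[0]
    while remaining:
        best = None
        for cand in remaining:
            cols = selected + [cand]
            if n <= len(cols) + 1:
                continue
            Xr = X_all[selected].values if selected else None
            F, p = _perm_f_test(Y, X_all[cols].values, Xr, 1, n_perm, rng)
            if best is None or (p, -F) < (best[1], -best[2]):
                best = (cand, p, F)
        if best is None or best[1] >= alpha_add:
            break
        selected.append(best[0])
        remaining.remove(best[0])
    return selected


# ---------------------------------------------------------------------------
# variance partitioning (vegan varpart style, Ezekiel adjustment)


def _r2_adj(response: np.ndarray, X: pd.DataFrame | None) -> float:
    if X is None or X.shape[1] == 0:
        return 0.0
    Y, pos_eig, _ = _pcoa_axes(response)
    total = float(pos_eig.sum())
    expl = _inertia_explained(Y, X.values)
    n = Y.shape[0]
    m = np.linalg.matrix_rank(X.values - X.values.mean(axis=0))
    r2 = expl / total
    if n - 1 - m <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 1 - m)


def variance_partition(response: np.ndarray, predictor_sets: dict) -> VarPartResult:
    """Partition adjusted R² into unique and shared fractions across 2–4 sets.

    ``predictor_sets`` maps set name -> DataFrame of columns.  Fractions follow
    inclusion–exclusion on the adjusted R² of every subset union; adjusted
    fractions may be slightly negative.
    """
    names = list(predictor_sets)
    if not (2 <= len(names) <= 4):
        raise ValueError("need 2–4 predictor sets")
    cols_seen: set = set()
    frames = {}
    for name in names:
        df = pd.DataFrame(predictor_sets[name]).astype(float)
        overlap = cols_seen & set(df.columns)
        if overlap:
            raise ValueError(f"column(s) {sorted(overlap)} appear in multiple sets")
        cols_seen |= set(df.columns)
        frames[name] = df

    D = np.asarray(response, dtype=float)
    r2 = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            X = _design_matrix(pd.concat([frames[c] for c in combo], axis=1))
            r2[frozenset(combo)] = _r2_adj(D, X)
    full = r2[frozenset(names)]

    # exclusive fraction of the Venn region covered by exactly the sets in S,
    # by Möbius inversion: f(S) = Σ_{W ⊆ S} (-1)^{|W|+1} R²adj((all \ S) ∪ W)
    # e.g. two sets: unique(A) = R2(AB) - R2(B); shared = R2(A)+R2(B)-R2(AB)
    exclusive = {}
    all_set = frozenset(names)
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            S = frozenset(combo)
            val = 0.0
            rest = all_set - S
            for j in range(0, len(combo) + 1):
                for sub in combinations(combo, j):
                    U = frozenset(sub) | rest
                    r = r2[U] if U else 0.0
                    val += (-1) ** (j + 1) * r
            exclusive[S] = val

    unique = {n: exclusive[frozenset([n])] for n in names}
    shared = {S: v for S, v in exclusive.items() if len(S) >= 2}
    residual = 1.0 - full
    return VarPartResult(
        set_names=names, unique=unique, shared=shared,
        residual=residual, r2_adj_full=full,
    )


def pearson_screen(predictors, threshold: float = 0.85) -> pd.DataFrame:
    """All pairwise Pearson correlations; |r| >= threshold flagged for manual drop."""
    X = pd.DataFrame(predictors).astype(float)
    if X.shape[1] < 2:
        raise ValueError("need >= 2 columns")
    sd = X.std(ddof=1)
    if (sd == 0).any():
        raise ValueError(f"constant column(s): {list(sd.index[sd == 0])}")
    rows = []
    cols = list(X.columns)
    corr = np.corrcoef(X.values.T)
    for i, j in combinations(range(len(cols)), 2):
        r = float(corr[i, j])
        rows.append(
            {"var_a": cols[i], "var_b": cols[j], "r": r,
             "flagged": abs(r) >= threshold}
        )
    return pd.DataFrame(rows)
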