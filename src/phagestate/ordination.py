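"""Ordination and environmental-driver machinery.

Bray-Curtis resemblance over transformed whole-genome expression,
non-metric MDS (Kruskal stress-1, SMACOF-style majorization with isotonic
regression, multiple restarts), least-squares environmental vector
fitting with permutation p-values, and the exhaustive BIOENV ("BEST")
search for the environmental-variable subset whose Euclidean distance
pattern maximally rank-correlates with the biological resemblance.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .containers import DataError, DistanceMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)


# --------------------------------------------------------------- Bray-Curtis

def bray_curtis(expr: ExpressionMatrix) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples over genes.

    d(i, j) = sum_g |x_gi - x_gj| / sum_g (x_gi + x_gj), in [0, 1]. A pair
    of all-zero samples has an undefined quotient and is defined as d = 0
    with a warning.
    """
    x = expr.values.to_numpy(dtype=float).T  # samples x genes
    if np.any(x < 0):
        raise DataError("Bray-Curtis requires non-negative values")
    if x.shape[0] < 2:
        raise DataError("need >= 2 samples")
    with np.errstate(invalid="ignore"):
        condensed = pdist(x, metric="braycurtis")
    if np.any(np.isnan(condensed)):
        logger.warning("all-zero sample pair(s): Bray-Curtis defined as 0")
        condensed = np.nan_to_num(condensed, nan=0.0)
    return DistanceMatrix(labels=[str(s) for s in expr.samples], d=squareform(condensed))


# ----------------------------------------------------------------------- nMDS

@dataclass
class Ordination:
    """A 2-D (by default) non-metric configuration with Kruskal stress-1."""

    coordinates: pd.DataFrame
    stress: float
    stress_trace: list[float]
    restarts_used: int
    converged: bool


def _kruskal_stress(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = float(np.sum(d**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((d - dhat) ** 2) / denom))


def _classical_mds(D: np.ndarray, n_dim: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:n_dim]
    w = np.clip(w[order], 0, None)
    return v[:, order] * np.sqrt(w)


def _smacof_nonmetric(
    D_condensed: np.ndarray,
    X0: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float, list[float], bool]:
    """Alternating isotonic regression + Guttman transform from one start.

    The reported trace is the stress-1 after each accepted iteration;
    iteration stops (previous configuration kept) as soon as stress fails
    to decrease, so the trace is non-increasing by construction.
    """
    n = X0.shape[0]
    iso = IsotonicRegression(increasing=True)
    X = X0 - X0.mean(axis=0)
    d = pdist(X)
    dhat = iso.fit_transform(D_condensed, d)
    stress = _kruskal_stress(d, dhat)
    trace = [stress]
    converged = False
    for _ in range(max_iter):
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, dhat / d, 0.0)
        R = squareform(ratio, checks=False)
        B = -R
        np.fill_diagonal(B, R.sum(axis=1))
        X_new = (B @ X) / n
        d_new = pdist(X_new)
        if np.linalg.norm(d_new) == 0:
            break
        dhat_new = iso.fit_transform(D_condensed, d_new)
        stress_new = _kruskal_stress(d_new, dhat_new)
        if stress_new > stress - 0.0:  # no improvement: keep previous X
            converged = stress - stress_new > -tol
            break
        X, d, dhat = X_new, d_new, dhat_new
        trace.append(stress_new)
        if stress - stress_new < tol:
            stress = stress_new
            converged = True
            break
        stress = stress_new
    return X, stress, trace, converged


def _principal_axis_rotate(X: np.ndarray) -> np.ndarray:
    X = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    X = X @ vt.T
    # fix reflection: largest-|coordinate| sample positive on each axis
    for j in range(X.shape[1]):
        i = np.argmax(np.abs(X[:, j]))
        if X[i, j] < 0:
            X[:, j] = -X[:, j]
    return X


def nmds(
    dist: DistanceMatrix,
    n_dim: int = 2,
    n_restarts: int = 50,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int = 0,
) -> Ordination:
    """Non-metric MDS minimizing Kruskal stress-1.

    The first restart starts from the classical (metric) scaling solution,
    the rest from seeded random configurations; the best (lowest-stress)
    restart is returned, centered and principal-axis rotated so the
    configuration is reproducible up to the rank information in the input.
    """
    if dist.n < 3:
        raise DataError("need >= 3 samples for an ordination")
    rng = np.random.default_rng(seed)
    Dc = dist.condensed()
    best: Optional[tuple[np.ndarray, float, list[float], bool]] = None
    for r in range(max(1, n_restarts)):
        X0 = (
            _classical_mds(dist.d, n_dim)
            if r == 0
            else rng.standard_normal((dist.n, n_dim))
        )
        res = _smacof_nonmetric(Dc, X0, max_iter, tol)
        if best is None or res[1] < best[1]:
            best = res
    X, stress, trace, converged = best
    X = _principal_axis_rotate(X)
    if not converged:
        logger.warning("nMDS did not converge in any restart (stress %.4f)", stress)
    return Ordination(
        coordinates=pd.DataFrame(
            X, index=dist.labels, columns=[f"axis{i+1}" for i in range(n_dim)]
        ),
        stress=stress,
        stress_trace=trace,
        restarts_used=max(1, n_restarts),
        converged=converged,
    )


# --------------------------------------------------------------------- envfit

def envfit(
    ord_: Ordination,
    env: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Least-squares environmental vectors on the ordination plane.

    For each variable: direction from regressing the standardized variable
    on the coordinates, length = multiple correlation R, permutation p
    from shuffling the variable across samples.
    """
    env = env.loc[ord_.coordinates.index]
    C = ord_.coordinates.to_numpy()
    C = C - C.mean(axis=0)
    Q, _ = np.linalg.qr(C)
    # one permutation set shared by all variables: p-values are then
    # invariant to column order and exactly sign-equivariant
    perms = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(len(env)) for _ in range(n_perm)])
    rows = []
    for var in env.columns:
        v = env[var].to_numpy(dtype=float)
        if np.unique(v).size < 2:
            logger.warning("envfit: variable %s is constant; skipped", var)
            continue
        vc = v - v.mean()
        ss = float(vc @ vc)
        r2 = float((Q.T @ vc) @ (Q.T @ vc) / ss)
        b, *_ = np.linalg.lstsq(C, vc, rcond=None)
        norm = np.linalg.norm(b)
        direction = b / norm if norm > 0 else b
        if n_perm > 0:
            Vp = vc[perms]  # already centered; permutation preserves mean
            proj = np.einsum("ij,bj->bi", Q.T, Vp)
            r2p = (proj**2).sum(axis=1) / ss
            p = float((1 + np.sum(r2p >= r2)) / (n_perm + 1))
        else:
            p = float("nan")
        R = float(np.sqrt(r2))
        rows.append(
            {
                "variable": var,
                "dx": direction[0] * R,
                "dy": (direction[1] * R) if len(direction) > 1 else 0.0,
                "R": R,
                "R2": r2,
                "p_value": p,
            }
        )
    return pd.DataFrame(
        rows, columns=["variable", "dx", "dy", "R", "R2", "p_value"]
    ).set_index("variable")


# --------------------------------------------------------------------- BIOENV

@dataclass
class BestResult:
    """Outcome of the exhaustive BIOENV environmental-subset search."""

    best_subset: tuple[str, ...]
    rho: float
    p_global: Optional[float]
    per_size_best: list[tuple[int, tuple[str, ...], float]] = field(
        default_factory=list
    )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"size": k, "subset": ",".join(sub), "rho": r}
            for k, sub, r in self.per_size_best
        ]
        return pd.DataFrame(rows).set_index("size")


def _pairwise_sq(z: np.ndarray) -> np.ndarray:
    """Per-variable condensed squared differences, shape (p, n_pairs)."""
    n, p = z.shape
    iu = np.triu_indices(n, k=1)
    diff = z[iu[0], :] - z[iu[1], :]
    return (diff**2).T


def _search_subsets(
    sq: np.ndarray,
    target_rank_z: np.ndarray,
    subsets: Sequence[tuple[int, ...]],
) -> np.ndarray:
    """Spearman rho of each candidate subset's distance with the target."""
    npairs = sq.shape[1]
    rhos = np.empty(len(subsets))
    for i, sub in enumerate(subsets):
        dsub = sq[list(sub)].sum(axis=0)  # sqrt omitted: rank-invariant
        r = stats.rankdata(dsub)
        r = (r - r.mean())
        denom = np.sqrt(float(r @ r))
        rhos[i] = float(r @ target_rank_z) / denom if denom > 0 else 0.0
    return rhos


def best_bioenv(
    dist: DistanceMatrix,
    env: pd.DataFrame,
    max_subset_size: Optional[int] = None,
    n_perm: int = 99,
    seed: int = 0,
) -> BestResult:
    """Exhaustive BIOENV: best env subset by Spearman rank correlation.

    Environmental variables are z-scored; candidate distance is Euclidean
    over the subset; rank correlation uses average ranks for ties. The
    global permutation p re-runs the full search on sample-permuted env
    tables and compares maximal rho values (set n_perm=0 to skip).
    """
    env = env.loc[dist.labels]
    if env.isna().any().any():
        bad = list(env.columns[env.isna().any()])
        raise DataError(
            f"missing environmental values in {bad}: impute or drop upstream"
        )
    p_vars = env.shape[1]
    if p_vars > 20:
        raise DataError("exhaustive search bounded at 20 candidate variables")
    if max_subset_size is None:
        max_subset_size = p_vars
    if max_subset_size < 1:
        raise DataError("max_subset_size must be >= 1")
    max_subset_size = min(max_subset_size, p_vars)

    z = env.to_numpy(dtype=float)
    sd = z.std(axis=0)
    if np.any(sd == 0):
        const = list(env.columns[sd == 0])
        logger.warning("constant environmental variables carry no signal: %s", const)
        sd = np.where(sd == 0, 1.0, sd)
    z = (z - z.mean(axis=0)) / sd

    target = stats.rankdata(dist.condensed())
    target = target - target.mean()
    target_z = target / np.sqrt(float(target @ target))

    subsets = [
        sub
        for k in range(1, max_subset_size + 1)
        for sub in itertools.combinations(range(p_vars), k)
    ]
    sq = _pairwise_sq(z)
    rhos = _search_subsets(sq, target_z, subsets)

    names = list(env.columns)
    per_size: list[tuple[int, tuple[str, ...], float]] = []
    for k in range(1, max_subset_size + 1):
        idxs = [i for i, s in enumerate(subsets) if len(s) == k]
        i_best = max(idxs, key=lambda i: rhos[i])
        per_size.append(
            (k, tuple(names[j] for j in subsets[i_best]), float(rhos[i_best]))
        )
    i_best = int(np.argmax(rhos))
    best_subset = tuple(names[j] for j in subsets[i_best])
    best_rho = float(rhos[i_best])

    p_global: Optional[float] = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(z.shape[0])
            sq_p = _pairwise_sq(z[perm])
            exceed += _search_subsets(sq_p, target_z, subsets).max() >= best_rho
        p_global = float((1 + exceed) / (n_perm + 1))
    return BestResult(
        best_subset=best_subset,
        rho=best_rho,
        p_global=p_global,
        per_size_best=per_size,
    )


# ------------------------------------------------------- similarity contours

def similarity_groups(
    dist: DistanceMatrix, thresholds: Sequence[float] = (0.4, 0.6, 0.8)
) -> pd.DataFrame:
    """Sample group membership at fixed similarity levels.

    Average-linkage clustering of the resemblance matrix, cut at
    dissimilarity 1 - threshold (the TSV analogue of the similarity
    contour ellipses drawn on ordination plots).
    """
    Z = hierarchy.linkage(dist.condensed(), method="average")
    out = {}
    for t in thresholds:
        labels = hierarchy.fcluster(Z, t=1.0 - t, criterion="distance")
        out[f"sim_{int(round(t * 100))}"] = labels
    return pd.DataFrame(out, index=dist.labels)
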