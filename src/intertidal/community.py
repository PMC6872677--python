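"""Beta diversity, ordination and matrix-correlation statistics.

Community dissimilarity is Bray-Curtis on log(x+1)-transformed rarefied
counts; ordination is non-metric multidimensional scaling (Kruskal stress-1);
group structure is tested by ANOSIM and matrix correlations by Mantel /
partial Mantel permutation tests (Spearman by default, 9999 permutations).
All permutation p-values carry the +1 correction and are never exactly 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import anosim as _skbio_anosim
from skbio.stats.distance import mantel as _skbio_mantel
from sklearn.manifold import MDS

from .io import OtuTable

logger = logging.getLogger(__name__)

__all__ = [
    "MatrixTestResult",
    "OrdinationResult",
    "PcaResult",
    "transform_community",
    "transform_env",
    "bray_curtis",
    "nmds",
    "anosim",
    "mantel",
    "partial_mantel",
    "geo_distance_matrix",
    "distance_decay",
    "pca_env",
    "env_group_test",
    "plot_nmds",
]

EARTH_RADIUS_KM = 6371.0

#: Variables exempt from the square-root transform: pH is a log-scale
#: quantity already, and the synthetic driver is a signed gradient.
SQRT_EXEMPT = ("pH", "env_driver")


@dataclass(frozen=True)
class MatrixTestResult:
    """Outcome of a permutation test on distance matrices."""

    statistic: float
    p_value: float
    n_permutations: int
    method: str
    n: int

    def __post_init__(self):
        if np.isfinite(self.statistic) and not -1 - 1e-9 <= self.statistic <= 1 + 1e-9:
            raise ValueError("statistic outside [-1, 1]")


@dataclass(frozen=True)
class OrdinationResult:
    coordinates: pd.DataFrame
    stress: float
    n_restarts: int
    converged: bool


@dataclass(frozen=True)
class PcaResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    proportion_explained: np.ndarray
    n_dropped: int


def transform_community(table: OtuTable) -> pd.DataFrame:
    """Element-wise log(count + 1) on the (rarefied) count table."""
    return np.log1p(table.data.astype(float))


def transform_env(meta: pd.DataFrame, variables=None) -> pd.DataFrame:
    """Square-root transform environmental variables (pH passed through)."""
    from .io import ENV_VARIABLES
    if variables is None:
        variables = [v for v in ENV_VARIABLES if v in meta.columns]
    out = {}
    for var in variables:
        col = meta[var].astype(float)
        if var in SQRT_EXEMPT:
            out[var] = col
            continue
        if (col.dropna() < 0).any():
            raise ValueError(f"negative value in sqrt-transformed variable {var!r}")
        out[var] = np.sqrt(col)
    return pd.DataFrame(out, index=meta.index)


def bray_curtis(matrix: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(x,y) = sum|x-y| / sum(x+y) between rows."""
    X = np.asarray(matrix, dtype=float)
    if np.any(X.sum(axis=1) == 0):
        bad = matrix.index[X.sum(axis=1) == 0]
        raise ValueError(f"all-zero sample(s) make Bray-Curtis undefined: "
                         f"{list(bad)[:5]}")
    return DistanceMatrix(squareform(pdist(X, metric="braycurtis"), checks=False),
                          ids=[str(i) for i in matrix.index])


def nmds(dist: DistanceMatrix, k: int = 2, n_restarts: int = 20,
         seed: int | None = None, max_iter: int = 300,
         eps: float = 1e-7) -> OrdinationResult:
    """Non-metric MDS minimising Kruskal stress-1; best of random restarts."""
    n = len(dist.ids)
    if k < 1 or n < k + 2:
        raise ValueError("need k >= 1 and at least k + 2 samples")
    model = MDS(n_components=k, metric_mds=False, metric="precomputed",
                n_init=n_restarts, init="random", max_iter=max_iter, eps=eps,
                random_state=None if seed is None else int(seed) % 2**32,
                normalized_stress=True)
    coords = model.fit_transform(dist.data)
    converged = model.n_iter_ < max_iter
    if not converged:
        logger.warning("NMDS did not converge within %d iterations", max_iter)
    cols = [f"NMDS{i + 1}" for i in range(k)]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(dist.ids), columns=cols),
        stress=float(model.stress_), n_restarts=n_restarts, converged=converged)


def anosim(dist: DistanceMatrix, groups: pd.Series, n_perm: int = 9999,
           seed: int | None = None) -> MatrixTestResult:
    """Analysis of similarities: rank-based between- vs within-group contrast.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2; the p-value permutes group labels (one-sided, R >= obs).
    """
    g = pd.Series(groups).loc[list(dist.ids)]
    sizes = g.value_counts()
    if len(sizes) < 2 or (sizes < 2).any():
        raise ValueError("ANOSIM needs >= 2 groups with >= 2 samples each")
    res = _skbio_anosim(dist, g.to_numpy(), permutations=n_perm, seed=seed)
    return MatrixTestResult(statistic=float(res["test statistic"]),
                            p_value=float(res["p-value"]),
                            n_permutations=n_perm, method="anosim",
                            n=len(g))


def _check_not_constant(dm: DistanceMatrix, name: str) -> None:
    if np.ptp(dm.condensed_form()) == 0:
        raise ValueError(f"distance matrix {name} is constant; "
                         "correlation undefined")


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 9999,
           method: str = "spearman", seed: int | None = None) -> MatrixTestResult:
    """Mantel correlation between two distance matrices (two-sided test).

    Permutes rows and columns of ``d2`` jointly; matrices are matched on ids.
    """
    _check_not_constant(d1, "d1")
    _check_not_constant(d2, "d2")
    r, p, n = _skbio_mantel(d1, d2, method=method, permutations=n_perm,
                            alternative="two-sided", strict=True, seed=seed)
    return MatrixTestResult(statistic=float(r), p_value=float(p),
                            n_permutations=n_perm, method=f"mantel-{method}", n=n)


def _condensed_index_matrix(n: int) -> np.ndarray:
    M = np.zeros((n, n), dtype=np.int64)
    iu = np.triu_indices(n, 1)
    M[iu] = np.arange(len(iu[0]))
    return M + M.T


def _standardized(vec: np.ndarray, method: str) -> np.ndarray:
    v = stats.rankdata(vec) if method == "spearman" else np.asarray(vec, float)
    sd = v.std()
    if sd == 0:
        raise ValueError("constant distance matrix; correlation undefined")
    return (v - v.mean()) / sd


def partial_mantel(d1: DistanceMatrix, d2: DistanceMatrix, d3: DistanceMatrix,
                   n_perm: int = 9999, method: str = "spearman",
                   seed: int | None = None) -> MatrixTestResult:
    """Partial Mantel correlation of d1 and d2 controlling for d3.

    Uses the first-order partial correlation
    r12.3 = (r12 - r13 r23) / sqrt((1 - r13^2)(1 - r23^2)) on the
    off-diagonal entries; the permutation distribution (two-sided, +1
    correction) permutes rows and columns of ``d2`` jointly, exactly as in
    the simple Mantel test.
    """
    ids = list(d1.ids)
    if list(d2.ids) != ids:
        d2 = d2.filter(ids)
    if list(d3.ids) != ids:
        d3 = d3.filter(ids)
    n = len(ids)
    iu = np.triu_indices(n, 1)
    u1 = _standardized(d1.condensed_form(), method)
    u2 = _standardized(d2.condensed_form(), method)
    u3 = _standardized(d3.condensed_form(), method)
    m = len(u1)

    def _partial(u2v: np.ndarray) -> float:
        r12 = float(u1 @ u2v) / m
        r13 = float(u1 @ u3) / m
        r23 = float(u2v @ u3) / m
        if abs(r13) >= 1 - 1e-12 or abs(r23) >= 1 - 1e-12:
            raise ValueError("degenerate control: |r13| or |r23| = 1")
        return (r12 - r13 * r23) / np.sqrt((1 - r13**2) * (1 - r23**2))

    obs = _partial(u2)
    M = _condensed_index_matrix(n)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gather = M[np.ix_(perm, perm)][iu]
        if abs(_partial(u2[gather])) >= abs(obs) - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return MatrixTestResult(statistic=float(obs), p_value=float(p),
                            n_permutations=n_perm,
                            method=f"partial-mantel-{method}", n=n)


def geo_distance_matrix(meta: pd.DataFrame, mode: str = "cartesian") -> DistanceMatrix:
    """Pairwise geographic distances (km) from longitude and latitude.

    ``cartesian`` projects to a local equirectangular plane and takes
    Euclidean distances (adequate over tens of km); ``haversine`` computes
    great-circle distances on a sphere of radius 6371 km.
    """
    if meta[["latitude", "longitude"]].isna().any().any():
        raise ValueError("missing coordinates")
    lat = np.radians(meta["latitude"].to_numpy(float))
    lon = np.radians(meta["longitude"].to_numpy(float))
    if mode == "haversine":
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        a = (np.sin(dlat / 2) ** 2 +
             np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2)
        D = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
        np.fill_diagonal(D, 0.0)
        D = (D + D.T) / 2
    elif mode == "cartesian":
        x = EARTH_RADIUS_KM * lon * np.cos(lat.mean())
        y = EARTH_RADIUS_KM * lat
        D = squareform(pdist(np.column_stack([x, y])), checks=False)
    else:
        raise ValueError("mode must be 'haversine' or 'cartesian'")
    return DistanceMatrix(D, ids=[str(i) for i in meta.index])


def distance_decay(comm: DistanceMatrix, geo: DistanceMatrix,
                   n_perm: int = 9999, seed: int | None = None) -> MatrixTestResult:
    """Spearman correlation of community similarity (1 - BC) with distance.

    Implemented as a Mantel test between the dissimilarity and distance
    matrices with the sign of r flipped (Spearman r of 1-d equals -r of d);
    the two-sided permutation p-value is unchanged.
    """
    res = mantel(comm, geo, n_perm=n_perm, method="spearman", seed=seed)
    return MatrixTestResult(statistic=-res.statistic, p_value=res.p_value,
                            n_permutations=n_perm, method="distance-decay",
                            n=res.n)


def pca_env(env: pd.DataFrame) -> PcaResult:
    """Centered, unit-variance PCA of the transformed environmental matrix.

    Rows with any missing value are dropped (logged); constant columns are
    excluded. Variance fractions over the retained components sum to 1.
    """
    complete = env.dropna()
    n_dropped = len(env) - len(complete)
    if n_dropped:
        logger.warning("pca_env: dropped %d row(s) with missing values", n_dropped)
    if len(complete) < 3:
        raise ValueError("fewer than 3 complete rows for PCA")
    X = complete.to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if keep.sum() < 2:
        raise ValueError("need >= 2 non-constant variables for PCA")
    cols = complete.columns[keep]
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    var = s**2
    frac = var / var.sum()
    k = len(s)
    pcs = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(U * s, index=complete.index, columns=pcs),
        loadings=pd.DataFrame(Vt.T, index=cols, columns=pcs),
        proportion_explained=frac, n_dropped=n_dropped)


def env_group_test(env: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Welch two-sample t-test per environmental variable across two groups."""
    g = pd.Series(groups).loc[env.index]
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ValueError("env_group_test expects exactly two groups")
    rows = {}
    for var in env.columns:
        a = env.loc[g == levels[0], var].dropna().to_numpy(float)
        b = env.loc[g == levels[1], var].dropna().to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            logger.warning("env_group_test: %s has a group with < 2 values", var)
            rows[var] = dict(t=np.nan, p=np.nan, n1=len(a), n2=len(b))
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows[var] = dict(t=float(t), p=float(p), n1=len(a), n2=len(b))
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "variable"
    return out


def plot_nmds(result: OrdinationResult, groups: pd.Series, path) -> None:
    """Minimal diagnostic NMDS scatter, coloured by group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    g = pd.Series(groups).loc[result.coordinates.index]
    for label in pd.unique(g):
        sub = result.coordinates[g == label]
        ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], label=str(label), s=25)
    ax.set_xlabel("NMDS1")
    ax.set_ylabel("NMDS2")
    ax.legend(fontsize=8)
    ax.set_title(f"stress = {result.stress:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
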