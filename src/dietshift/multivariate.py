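"""Permutation-based multivariate inference on dissimilarity matrices.

perMANOVA with sequential sums of squares over a species/season/interaction
design, homogeneity of multivariate dispersions with principal-coordinate
embedding and negative-eigenvalue correction, Mantel matrix correlation,
and non-metric multidimensional scaling. All permutation p-values use the
(1 + exceedances) / (1 + n_perm) estimator; small problems are enumerated
exhaustively so the p-value is exact.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from skbio.stats.distance import DistanceMatrix
from sklearn.isotonic import IsotonicRegression

#: Largest number of permutations enumerated exhaustively instead of sampled.
MAX_EXHAUSTIVE = 10_000

_EIG_TOL = 1e-8


def _as_square(D) -> np.ndarray:
    if isinstance(D, DistanceMatrix):
        return np.asarray(D.data, dtype=float)
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    return D


def _gower_center(D: np.ndarray) -> np.ndarray:
    """G = -1/2 C D^2 C with C the centring operator I - 11'/n."""
    A = -0.5 * D * D
    n = A.shape[0]
    row = A.mean(axis=0)
    return A - row[None, :] - row[:, None] + row.mean()


def _permutations(n: int, n_perm: int, seed):
    """Yield (perms, exact): exhaustive if n! <= MAX_EXHAUSTIVE, else sampled."""
    if math.factorial(n) <= MAX_EXHAUSTIVE:
        return [np.array(p) for p in itertools.permutations(range(n))], True
    rng = np.random.default_rng(seed)
    return [rng.permutation(n) for _ in range(n_perm)], False


def _perm_pvalue(obs: float, perm_stats: np.ndarray, exact: bool) -> float:
    """(1 + #{perm >= obs}) / (1 + n) for sampled draws; under exhaustive
    enumeration the identity permutation is one of the draws, giving the
    exact orbit proportion."""
    ge = int(np.sum(perm_stats >= obs - 1e-12))
    if exact:
        return ge / len(perm_stats)
    return (1 + ge) / (1 + len(perm_stats))


# ---------------------------------------------------------------------------
# perMANOVA


@dataclass
class PermanovaResult:
    """Per-term partition of a distance matrix (adonis2-style, sequential SS)."""

    table: pd.DataFrame  # rows: terms + Residual + Total; cols df, SS, F, R2, p
    n_permutations: int
    exact: bool
    seed: int | None

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return self.table.to_string()


def _design_spaces(factors: pd.DataFrame, terms: list[str]) -> list[np.ndarray]:
    """Column blocks spanning each term's design space (coding-invariant)."""
    blocks = []
    for term in terms:
        parts = term.split(":")
        if not all(p in factors.columns for p in parts):
            raise ValueError(f"unknown factor in term {term!r}")
        cells = factors[parts].astype(str).agg("|".join, axis=1)
        blocks.append(pd.get_dummies(cells).values.astype(float))
    return blocks


def permanova(
    D,
    factors,
    terms: list[str] | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Permutational MANOVA of a distance matrix against design factors.

    The squared, Gower-centred matrix ``G`` is partitioned sequentially by
    the model terms (default: every factor then all-way interaction when
    two factors are given); each term's pseudo-F is
    (SS_term/df_term) / (SS_res/df_res) and its p-value comes from
    whole-row permutation of the samples.
    """
    Dm = _as_square(D)
    n = Dm.shape[0]
    factors = pd.DataFrame(factors)
    if len(factors) != n:
        raise ValueError("factor table length does not match distance matrix")
    for c in factors.columns:
        if factors[c].nunique() < 2:
            raise ValueError(f"factor {c!r} has fewer than 2 levels")
    if terms is None:
        terms = list(factors.columns)
        if len(factors.columns) == 2:
            terms.append(":".join(factors.columns))

    G = _gower_center(Dm)
    blocks = _design_spaces(factors, terms)

    # cumulative orthonormal bases (intercept first)
    ones = np.full((n, 1), 1.0 / np.sqrt(n))
    bases, ranks = [], []
    X = ones
    for B in blocks:
        X = np.hstack([X, B])
        # SVD-based orthonormal basis: dummy blocks are rank deficient, and
        # unpivoted QR misbehaves on interior dependent columns
        U, s, _ = np.linalg.svd(X, full_matrices=False)
        keep = s > 1e-9 * s.max()
        bases.append(U[:, keep])
        ranks.append(int(keep.sum()))
    rank0 = [1] + ranks[:-1]
    dfs = [r1 - r0 for r0, r1 in zip(rank0, ranks)]
    if any(d == 0 for d in dfs):
        raise ValueError("confounded terms: a term adds no degrees of freedom")
    df_res = n - ranks[-1]
    if df_res <= 0:
        raise ValueError("zero residual degrees of freedom")

    def term_stats(Gp):
        tr_prev = (ones * (Gp @ ones)).sum()
        ss = []
        for Q in bases:
            tr = np.einsum("ij,ij->", Q, Gp @ Q)
            ss.append(tr - tr_prev)
            tr_prev = tr
        ss = np.array(ss)
        ss_total = np.trace(Gp)
        ss_res = ss_total - tr_prev
        F = (ss / np.array(dfs)) / (ss_res / df_res)
        return ss, ss_res, ss_total, F

    ss, ss_res, ss_total, F_obs = term_stats(G)

    perms, exact = _permutations(n, n_perm, seed)
    perm_F = np.empty((len(perms), len(terms)))
    for k, p in enumerate(perms):
        perm_F[k] = term_stats(G[np.ix_(p, p)])[3]
    pvals = [_perm_pvalue(F_obs[j], perm_F[:, j], exact) for j in range(len(terms))]

    rows = []
    for j, t in enumerate(terms):
        rows.append([t, dfs[j], ss[j], F_obs[j], ss[j] / ss_total, pvals[j]])
    rows.append(["Residual", df_res, ss_res, np.nan, ss_res / ss_total, np.nan])
    rows.append(["Total", n - 1, ss_total, np.nan, 1.0, np.nan])
    table = pd.DataFrame(rows, columns=["term", "df", "SS", "F", "R2", "p"]).set_index("term")
    return PermanovaResult(table=table, n_permutations=len(perms), exact=exact, seed=seed)


# ---------------------------------------------------------------------------
# multivariate dispersion (betadisper-style)


@dataclass
class DispersionResult:
    """Distances of samples to their group centre in PCoA space."""

    distances: pd.Series          # per-sample distance to own group centre
    group_means: pd.Series        # mean dispersion per group
    groups: pd.Series
    F: float
    centre_type: str
    bias_adjusted: bool


def _pcoa_axes(D: np.ndarray):
    G = _gower_center(D)
    vals, vecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scale = max(1.0, np.abs(vals).max())
    pos = vals > _EIG_TOL * scale
    neg = vals < -_EIG_TOL * scale
    real = vecs[:, pos] * np.sqrt(vals[pos])
    imag = vecs[:, neg] * np.sqrt(-vals[neg])
    return real, imag


def _spatial_median(X: np.ndarray, max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Weiszfeld iteration for the geometric median of rows of X."""
    m = X.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(X - m, axis=1)
        if (d < 1e-12).any():
            # median coincides with a data point: it is optimal if the
            # pulled gradient of the others is small; accept the point
            return X[np.argmin(d)].copy()
        w = 1.0 / d
        new = (X * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(new - m) < tol:
            return new
        m = new
    return m


def dispersion(
    D,
    groups,
    centre_type: str = "median",
    bias_adjust: bool = True,
) -> DispersionResult:
    """Multivariate dispersion: distance of each sample to its group centre.

    The distance matrix is embedded by principal coordinates keeping
    imaginary axes; squared distances are real-part minus imaginary-part,
    floored at zero, so non-Euclidean (e.g. Bray-Curtis) matrices are
    handled without distortion. ``centre_type`` is ``"median"`` (spatial
    median, the default) or ``"centroid"``. Bias adjustment scales group-g
    distances by sqrt(n_g / (n_g - 1)).
    """
    Dm = _as_square(D)
    if isinstance(D, DistanceMatrix):
        ids = list(D.ids)
    else:
        ids = list(pd.Series(groups).index) if isinstance(groups, pd.Series) else list(range(len(Dm)))
    groups = pd.Series(np.asarray(groups), index=ids, name="group")
    sizes = groups.value_counts()
    if (sizes < 2).any():
        raise ValueError(f"groups of size 1: {list(sizes.index[sizes < 2])}")

    real, imag = _pcoa_axes(Dm)
    coords = np.hstack([real, imag])
    n_real = real.shape[1]

    z = np.empty(len(groups))
    for g, idx in groups.groupby(groups).groups.items():
        sel = groups.index.get_indexer(idx)
        sub = coords[sel]
        if centre_type == "centroid":
            centre = sub.mean(axis=0)
        elif centre_type == "median":
            # geometric medians of the real and imaginary subspaces are
            # found separately (the two parts enter the distance with
            # opposite signs)
            centre = np.concatenate(
                [_spatial_median(sub[:, :n_real]), _spatial_median(sub[:, n_real:])]
            )
        else:
            raise ValueError("centre_type must be 'median' or 'centroid'")
        diff = coords[sel] - centre
        d2 = (diff[:, :n_real] ** 2).sum(axis=1) - (diff[:, n_real:] ** 2).sum(axis=1)
        z[sel] = np.sqrt(np.maximum(d2, 0.0))
    if bias_adjust:
        adj = groups.map(np.sqrt(sizes / (sizes - 1.0)))
        z = z * adj.values

    dist = pd.Series(z, index=groups.index, name="distance")
    F = _anova_f(dist.values, groups.values)
    return DispersionResult(
        distances=dist,
        group_means=dist.groupby(groups).mean(),
        groups=groups,
        F=F,
        centre_type=centre_type,
        bias_adjusted=bias_adjust,
    )


def _anova_f(y: np.ndarray, g: np.ndarray) -> float:
    codes, _ = pd.factorize(g)
    k = codes.max() + 1
    n = len(y)
    grand = y.mean()
    ss_b = 0.0
    ss_w = 0.0
    for j in range(k):
        yj = y[codes == j]
        ss_b += len(yj) * (yj.mean() - grand) ** 2
        ss_w += ((yj - yj.mean()) ** 2).sum()
    if ss_w == 0:
        return np.inf if ss_b > 0 else 0.0
    return (ss_b / (k - 1)) / (ss_w / (n - k))


def permutest(result: DispersionResult, n_perm: int = 999, seed: int | None = None) -> float:
    """Permutation p-value for equality of group mean dispersions.

    Model residuals (distance minus own-group mean) are permuted and refit
    against the group design; permuting residuals rather than raw distances
    keeps the test calibrated when group means differ.
    """
    y = result.distances.values
    g = result.groups.values
    codes, _ = pd.factorize(g)
    group_means = np.array([y[codes == j].mean() for j in range(codes.max() + 1)])
    resid = y - group_means[codes]
    perms, exact = _permutations(len(y), n_perm, seed)
    stats = np.array([_anova_f(resid[p], g) for p in perms])
    return _perm_pvalue(result.F, stats, exact)


# ---------------------------------------------------------------------------
# Mantel


def mantel(D1, D2, n_perm: int = 999, seed: int | None = None) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    Pearson r over the lower triangles; significance by simultaneous
    row/column permutation of the second matrix.
    """
    A = _as_square(D1)
    B = _as_square(D2)
    if isinstance(D1, DistanceMatrix) and isinstance(D2, DistanceMatrix):
        if list(D1.ids) != list(D2.ids):
            raise ValueError("distance matrices have different labels")
    if A.shape != B.shape:
        raise ValueError("distance matrices differ in size")
    a = squareform(A, checks=False)
    tril = np.tril_indices(A.shape[0], k=-1)
    if np.std(a) == 0 or np.std(B[tril]) == 0:
        raise ValueError("zero variance in a distance triangle")

    a = (a - a.mean()) / a.std()

    def corr(Bp):
        b = squareform(Bp, checks=False)
        return float(np.mean(a * (b - b.mean()) / b.std()))

    r_obs = corr(B)
    perms, exact = _permutations(A.shape[0], n_perm, seed)
    stats = np.array([corr(B[np.ix_(p, p)]) for p in perms])
    p = _perm_pvalue(r_obs, stats, exact)
    return r_obs, p


# ---------------------------------------------------------------------------
# NMDS


@dataclass
class NmdsResult:
    """Non-metric MDS configuration with its Kruskal stress-1."""

    coordinates: np.ndarray
    stress: float
    stress_sequence: list = field(default_factory=list)
    n_restarts: int = 1
    converged: bool = True


def _nmds_once(D, k, rng, init, max_iter, tol):
    n = D.shape[0]
    iu = np.triu_indices(n, 1)
    delta = D[iu]
    order = np.argsort(delta, kind="stable")
    iso = IsotonicRegression(increasing=True)
    X = init.copy()
    bestX = X.copy()
    stresses = []
    prev = np.inf
    for _ in range(max_iter):
        dX = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
        d = dX[iu]
        dhat = iso.fit(delta[order], d[order]).predict(delta)
        denom = (d * d).sum()
        stress = np.sqrt(((d - dhat) ** 2).sum() / denom) if denom > 0 else 0.0
        if stress > prev + 1e-12:
            break
        stresses.append(stress)
        bestX = X.copy()
        if prev - stress < tol:
            prev = stress
            break
        prev = stress
        # Guttman transform toward the disparities
        Dhat = np.zeros_like(dX)
        Dhat[iu] = dhat
        Dhat = Dhat + Dhat.T
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dX > 0, Dhat / dX, 0.0)
        B = -ratio
        np.fill_diagonal(B, ratio.sum(axis=1))
        X = (B @ X) / n
        X = X - X.mean(axis=0)
    return bestX, prev, stresses


def nmds(
    D,
    k: int = 2,
    n_restarts: int = 8,
    max_iter: int = 300,
    seed: int | None = None,
    tol: float = 1e-7,
) -> NmdsResult:
    """Non-metric multidimensional scaling of a distance matrix.

    Kruskal stress-1 is minimized by alternating isotonic regression of the
    embedded distances on the dissimilarity ranks with SMACOF (Guttman)
    configuration updates; the best of ``n_restarts`` starts (principal
    coordinates plus random) is returned.
    """
    Dm = _as_square(D)
    n = Dm.shape[0]
    if k >= n:
        raise ValueError("k must be < number of samples")
    rng = np.random.default_rng(seed)
    inits = []
    real, _ = _pcoa_axes(Dm)
    if real.shape[1] >= 1:
        pad = np.zeros((n, max(0, k - real.shape[1])))
        inits.append(np.hstack([real[:, :k], pad]))
    while len(inits) < n_restarts:
        inits.append(rng.normal(size=(n, k)))
    best = None
    for init in inits:
        X, stress, seq = _nmds_once(Dm, k, rng, init, max_iter, tol)
        if best is None or stress < best.stress:
            best = NmdsResult(
                coordinates=X,
                stress=float(stress),
                stress_sequence=seq,
                n_restarts=n_restarts,
                converged=len(seq) < max_iter,
            )
    return best
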