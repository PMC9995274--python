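"""Phylogenetically controlled regressions and effective population size.

PGLS fits a linear model by generalized least squares with an error
covariance proportional to shared branch lengths under Brownian motion
on a time-calibrated ultrametric tree (Pagel's lambda fixed at 1 by
default; optional ML estimation of lambda).  On a star phylogeny the
covariance is diagonal and PGLS reduces exactly to OLS.

Effective population size utilities: the time-weighted harmonic mean of
a piecewise-constant Ne trajectory over a window (the summary used with
PSMC-style step functions), and the neutral-theory point estimate
Ne = pi / (4 mu).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from sklearn.base import BaseEstimator

__all__ = [
    "PGLS",
    "PGLSFit",
    "NeTrajectory",
    "phylo_covariance",
    "pgls_fit",
    "ols_adjusted_r2",
    "harmonic_mean_ne",
    "ne_from_pi",
]


@dataclass
class PGLSFit:
    """Result of a phylogenetic (or ordinary) least-squares regression."""

    slope: float
    intercept: float
    adjusted_r2: float
    p_value: float
    r2: float
    residual_variance: float
    lam: float
    n: int
    coefficients: dict[str, float] = field(default_factory=dict)


def check_ultrametric(tree: dendropy.Tree, tol: float = 1e-6) -> bool:
    """True when all root-to-tip distances agree to within ``tol`` (relative)."""
    depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
    span = max(depths) - min(depths)
    scale = max(max(depths), 1e-300)
    return span / scale <= tol


def phylo_covariance(tree: dendropy.Tree, taxa: Sequence[str]) -> np.ndarray:
    """Brownian-motion covariance: shared root-to-MRCA branch length.

    Off-diagonal (i, j) entries are the depth of the most recent common
    ancestor of tips i and j; diagonal entries are root-to-tip distances.
    """
    labels = [t.taxon.label for t in tree.leaf_node_iter()]
    missing = [t for t in taxa if t not in labels]
    if missing:
        raise ValueError(f"species missing from tree: {missing}")
    pdm = tree.phylogenetic_distance_matrix()
    tns = tree.taxon_namespace
    taxon = {t.label: t for t in tns if t.label in set(taxa)}
    depth = {
        leaf.taxon.label: leaf.distance_from_root()
        for leaf in tree.leaf_node_iter()
        if leaf.taxon.label in set(taxa)
    }
    n = len(taxa)
    cov = np.zeros((n, n))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i == j:
                cov[i, j] = depth[a]
            else:
                # shared path = (d_root(a) + d_root(b) - patristic(a,b)) / 2
                d = pdm.patristic_distance(taxon[a], taxon[b])
                cov[i, j] = 0.5 * (depth[a] + depth[b] - d)
    return cov


def _lambda_transform(cov: np.ndarray, lam: float) -> np.ndarray:
    out = cov * lam
    np.fill_diagonal(out, np.diag(cov))
    return out


class PGLS(BaseEstimator):
    """Phylogenetic generalized least squares, sklearn-style.

    Parameters
    ----------
    lam : float, default 1.0
        Pagel's lambda scaling the off-diagonal covariance. 1.0 is pure
        Brownian motion; 0.0 collapses to OLS.
    estimate_lambda : bool, default False
        Maximize the GLS profile likelihood over lambda in [0, 1]
        instead of using the fixed value.

    Attributes (after :meth:`fit`)
    ------------------------------
    slope_, intercept_, adjusted_r2_, p_value_, lam_ : floats
    result_ : statsmodels GLS results object
    """

    def __init__(self, lam: float = 1.0, estimate_lambda: bool = False):
        self.lam = lam
        self.estimate_lambda = estimate_lambda

    def fit(self, x, y, tree: dendropy.Tree | None = None, taxa: Sequence[str] | None = None):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        n = len(y)
        if n < 4:
            raise ValueError("PGLS needs at least 4 species")
        if tree is None:
            cov = np.eye(n)
        else:
            if taxa is None:
                raise ValueError("taxa (tip labels aligned with x, y) required with a tree")
            cov = phylo_covariance(tree, list(taxa))

        if self.estimate_lambda and tree is not None:
            self.lam_ = self._profile_lambda(x, y, cov)
        else:
            self.lam_ = float(self.lam)
        sigma = _lambda_transform(cov, self.lam_)
        X = sm.add_constant(x)
        res = sm.GLS(y, X, sigma=sigma).fit()
        self.result_ = res
        self.intercept_ = float(res.params[0])
        self.slope_ = float(res.params[1])
        self.coefficients_ = dict(zip(res.model.exog_names, map(float, res.params)))
        self.r2_ = float(res.rsquared)
        self.adjusted_r2_ = float(res.rsquared_adj)
        self.p_value_ = float(res.pvalues[1])
        self.residual_variance_ = float(res.scale)
        self.n_ = n
        return self

    @staticmethod
    def _profile_lambda(x: np.ndarray, y: np.ndarray, cov: np.ndarray) -> float:
        X = sm.add_constant(x)

        def nll(lam):
            res = sm.GLS(y, X, sigma=_lambda_transform(cov, float(lam))).fit()
            return -res.llf

        res = optimize.minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded")
        return float(res.x)

    def to_fit(self) -> PGLSFit:
        return PGLSFit(
            slope=self.slope_,
            intercept=self.intercept_,
            adjusted_r2=self.adjusted_r2_,
            p_value=self.p_value_,
            r2=self.r2_,
            residual_variance=self.residual_variance_,
            lam=self.lam_,
            n=self.n_,
            coefficients=self.coefficients_,
        )


def pgls_fit(
    x,
    y,
    tree: dendropy.Tree,
    taxa: Sequence[str],
    lam: float = 1.0,
    estimate_lambda: bool = False,
) -> PGLSFit:
    """Fit y ~ x by PGLS under Brownian motion on ``tree``.

    ``taxa`` are the tip labels aligned with the rows of x and y; the
    covariance is built on exactly that subset of tips.
    """
    return PGLS(lam=lam, estimate_lambda=estimate_lambda).fit(x, y, tree=tree, taxa=taxa).to_fit()


def ols_adjusted_r2(x, y) -> tuple[float, float, float]:
    """Ordinary least squares; returns (slope, adjusted r^2, p-value of slope)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in x")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return float(res.params[1]), float(res.rsquared_adj), float(res.pvalues[1])


@dataclass
class NeTrajectory:
    """Piecewise-constant Ne history, years before present.

    Segments are (t_start, t_end, Ne) with t_start < t_end, ordered and
    non-overlapping.
    """

    segments: list[tuple[float, float, float]]
    species: str = ""

    def __post_init__(self):
        segs = sorted(self.segments)
        for (s0, e0, n0), (s1, _, _) in zip(segs, segs[1:]):
            if e0 > s1 + 1e-9:
                raise ValueError("overlapping Ne segments")
        for s, e, ne in segs:
            if e <= s:
                raise ValueError("segment end must exceed start")
            if ne <= 0:
                raise ValueError("Ne must be positive")
        self.segments = segs

    @property
    def support(self) -> tuple[float, float]:
        return self.segments[0][0], self.segments[-1][1]


def harmonic_mean_ne(traj: NeTrajectory, window_start: float, window_end: float) -> float:
    """Time-weighted harmonic mean Ne over [window_start, window_end].

    Partial overlaps are clipped to the window; the mean is
    (total overlapped time) / (integral of dt / Ne(t)).
    """
    if window_end <= window_start:
        raise ValueError("window_end must exceed window_start")
    total_t = 0.0
    integral = 0.0
    for s, e, ne in traj.segments:
        lo, hi = max(s, window_start), min(e, window_end)
        if hi > lo:
            total_t += hi - lo
            integral += (hi - lo) / ne
    if total_t == 0.0:
        raise ValueError("window does not overlap the Ne trajectory support")
    return total_t / integral


def ne_from_pi(pi: float, mu: float) -> float:
    """Neutral-theory effective population size: Ne = pi / (4 mu)."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if pi < 0:
        raise ValueError("pi must be non-negative")
    return pi / (4.0 * mu)
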