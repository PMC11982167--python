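"""GREML: SNP-based heritability and genetic correlations.

Univariate model: y = mu + g + e with g ~ N(0, vg G) and e ~ N(0, ve I),
estimated by REML after an eigendecomposition of the GRM, which reduces the
likelihood to independent 1-D Gaussian terms. The heritability
h2 = vg / (vg + ve) is found by a profile search on [0, 1] (grid plus
bounded refinement); its standard error comes from the numerical curvature
of the profile REML log-likelihood.

Bivariate model: the same rotation factorises the joint likelihood of two
traits into per-eigenvalue 2x2 Gaussian blocks with covariance
d_i * Vg + Ve; Vg and Ve are optimised through their Cholesky factors and
the genetic correlation is rg = Vg12 / sqrt(Vg11 Vg22).

Averaging across trials and two-group clustering of the averaged genetic
correlation matrix reproduce the element-grouping procedure used to define
the meta-analysis designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .datatypes import Grm

__all__ = [
    "GREML", "GREMLResults", "BivariateGREML", "BivariateGREMLResults",
    "greml_univariate", "greml_bivariate", "dense_reml_loglik",
    "average_rg", "group_elements", "ElementGrouping",
]


# ---------------------------------------------------------------------------
# univariate
# ---------------------------------------------------------------------------

def _align(y, grm: Grm, lines=None):
    y = np.asarray(y, dtype=float)
    if lines is not None:
        idx = {l: i for i, l in enumerate(grm.lines)}
        sel = np.array([idx[l] for l in lines])
        G = grm.values[np.ix_(sel, sel)]
    else:
        if y.size != len(grm.lines):
            raise ValueError("phenotype length does not match GRM")
        G = grm.values
    ok = ~np.isnan(y)
    return y[ok], G[np.ix_(np.flatnonzero(ok), np.flatnonzero(ok))]


@dataclass
class GREMLResults:
    vg: float
    ve: float
    h2: float
    se_h2: float
    loglik: float
    converged: bool
    n: int

    def summary(self) -> str:
        return (
            f"GREML (n={self.n})\n"
            f"  vg = {self.vg:.6g}   ve = {self.ve:.6g}\n"
            f"  h2 = {self.h2:.4f}  (se {self.se_h2:.4f})\n"
            f"  REML log-likelihood = {self.loglik:.4f}  converged={self.converged}"
        )


class GREML:
    """Univariate GREML model for one trait and one GRM."""

    def __init__(self, y, grm: Grm, lines=None):
        self.y, G = _align(y, grm, lines)
        self.n = self.y.size
        if self.n < 5:
            raise ValueError("too few lines with phenotype and GRM entry")
        self.d, U = np.linalg.eigh(G)
        self.d = np.clip(self.d, 0.0, None)
        self.ystar = U.T @ self.y
        self.xstar = U.T @ np.ones(self.n)

    @classmethod
    def from_rotation(cls, d, ystar, xstar) -> "GREML":
        """Build from a precomputed eigen-rotation (d, U'y, U'1)."""
        self = cls.__new__(cls)
        self.d = np.clip(np.asarray(d, dtype=float), 0.0, None)
        self.ystar = np.asarray(ystar, dtype=float)
        self.xstar = np.asarray(xstar, dtype=float)
        self.n = self.ystar.size
        return self

    def profile_loglik(self, h2: float):
        """Full-constant REML log-likelihood profiled over total variance."""
        c = h2 * self.d + (1.0 - h2)
        if (c <= 0).any():
            return -np.inf, np.nan, np.nan
        w = 1.0 / c
        sxx = np.sum(w * self.xstar ** 2)
        sxy = np.sum(w * self.xstar * self.ystar)
        syy = np.sum(w * self.ystar ** 2)
        rss = syy - sxy * sxy / sxx
        dof = self.n - 1
        s = rss / dof   # total variance vg + ve
        if s <= 0:
            return -np.inf, np.nan, np.nan
        ll = -0.5 * (dof * (np.log(2 * np.pi * s) + 1.0)
                     + np.log(c).sum() + np.log(sxx))
        return ll, s, sxy / sxx

    def fit(self, grid_points: int = 41) -> GREMLResults:
        grid = np.linspace(0.0, 1.0 - 1e-9, grid_points)
        lls = np.array([self.profile_loglik(h)[0] for h in grid])
        j = int(np.nanargmax(lls))
        lo = grid[max(j - 1, 0)]
        hi = grid[min(j + 1, grid.size - 1)]
        res = optimize.minimize_scalar(lambda h: -self.profile_loglik(h)[0],
                                       bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-8})
        h2 = float(res.x)
        ll, s, _ = self.profile_loglik(h2)
        # prefer an exact boundary when it is as good
        for b in (0.0, 1.0 - 1e-9):
            llb, sb, _ = self.profile_loglik(b)
            if llb > ll + 1e-9:
                h2, ll, s = b, llb, sb
        boundary = h2 < 1e-6 or h2 > 1 - 1e-6
        # curvature-based standard error
        eps = 1e-4
        if eps < h2 < 1 - eps:
            l0 = self.profile_loglik(h2 - eps)[0]
            l1 = self.profile_loglik(h2 + eps)[0]
            curv = (l0 - 2 * ll + l1) / eps ** 2
            se = float(1.0 / np.sqrt(-curv)) if curv < 0 else float("nan")
        else:
            se = float("nan")
        h2 = min(max(h2, 0.0), 1.0)
        return GREMLResults(vg=float(h2 * s), ve=float((1 - h2) * s), h2=h2,
                            se_h2=se, loglik=float(ll),
                            converged=not boundary, n=self.n)


def greml_univariate(y, grm: Grm, lines=None) -> GREMLResults:
    return GREML(y, grm, lines=lines).fit()


def dense_reml_loglik(y: np.ndarray, G: np.ndarray, vg: float, ve: float) -> float:
    """Direct dense REML log-likelihood (intercept-only fixed effects).

    Brute-force reference: V = vg G + ve I evaluated with explicit
    determinants, same additive constants as the eigen-form likelihood.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    V = vg * G + ve * np.eye(n)
    sign, logdet_V = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    x = np.ones(n)
    Vi_x = np.linalg.solve(V, x)
    xtVix = float(x @ Vi_x)
    beta = float(Vi_x @ y) / xtVix
    r = y - beta
    quad = float(r @ np.linalg.solve(V, r))
    return float(-0.5 * ((n - 1) * np.log(2 * np.pi) + logdet_V
                         + np.log(xtVix) + quad))


# ---------------------------------------------------------------------------
# bivariate
# ---------------------------------------------------------------------------

@dataclass
class BivariateGREMLResults:
    vg: np.ndarray           # 2x2 genetic covariance
    ve: np.ndarray           # 2x2 residual covariance
    rg: float
    h2: tuple
    loglik: float
    converged: bool
    clipped: bool
    n: int

    def summary(self) -> str:
        return (
            f"Bivariate GREML (n={self.n})\n"
            f"  Vg = {np.array2string(self.vg, precision=4)}\n"
            f"  Ve = {np.array2string(self.ve, precision=4)}\n"
            f"  h2 = ({self.h2[0]:.4f}, {self.h2[1]:.4f})   rg = {self.rg:.4f}\n"
            f"  log-likelihood = {self.loglik:.4f}  converged={self.converged}"
        )


class BivariateGREML:
    """Bivariate GREML for two traits sharing one GRM (complete-case lines)."""

    def __init__(self, y1, y2, grm: Grm, lines=None):
        y1 = np.asarray(y1, dtype=float)
        y2 = np.asarray(y2, dtype=float)
        if lines is None and (y1.size != len(grm.lines) or y2.size != len(grm.lines)):
            raise ValueError("phenotype length does not match GRM")
        G = grm.values if lines is None else grm.subset_lines(lines).values
        ok = ~(np.isnan(y1) | np.isnan(y2))
        if ok.sum() < 10:
            raise ValueError("too few lines observed for both traits")
        idx = np.flatnonzero(ok)
        G = G[np.ix_(idx, idx)]
        self.n = idx.size
        self.d, U = np.linalg.eigh(G)
        self.d = np.clip(self.d, 0.0, None)
        self.Y = np.column_stack([U.T @ y1[ok], U.T @ y2[ok]])  # n x 2
        self.x = U.T @ np.ones(self.n)                          # n

    # -- likelihood -------------------------------------------------------
    def _covs(self, theta):
        """theta -> (Vg, Ve) via Cholesky factors with log-diagonals."""
        lg = np.array([[np.exp(theta[0]), 0.0], [theta[1], np.exp(theta[2])]])
        le = np.array([[np.exp(theta[3]), 0.0], [theta[4], np.exp(theta[5])]])
        return lg @ lg.T, le @ le.T

    def loglik(self, theta) -> float:
        Vg, Ve = self._covs(theta)
        # per-eigenvalue 2x2 covariance: S_i = d_i Vg + Ve
        a = self.d * Vg[0, 0] + Ve[0, 0]
        b = self.d * Vg[0, 1] + Ve[0, 1]
        c = self.d * Vg[1, 1] + Ve[1, 1]
        det = a * c - b * b
        if (det <= 0).any() or (a <= 0).any():
            return -np.inf
        ia, ib, ic = c / det, -b / det, a / det
        y1, y2 = self.Y[:, 0], self.Y[:, 1]
        x2 = self.x ** 2
        # GLS for the two intercepts: A = sum x_i^2 Sigma_i^-1 (2x2)
        A = np.array([[np.sum(x2 * ia), np.sum(x2 * ib)],
                      [np.sum(x2 * ib), np.sum(x2 * ic)]])
        rhs = np.array([np.sum(self.x * (ia * y1 + ib * y2)),
                        np.sum(self.x * (ib * y1 + ic * y2))])
        detA = A[0, 0] * A[1, 1] - A[0, 1] ** 2
        if detA <= 0:
            return -np.inf
        mu = np.linalg.solve(A, rhs)
        r1 = y1 - self.x * mu[0]
        r2 = y2 - self.x * mu[1]
        quad = np.sum(ia * r1 * r1 + 2 * ib * r1 * r2 + ic * r2 * r2)
        return float(-0.5 * ((2 * self.n - 2) * np.log(2 * np.pi)
                             + np.log(det).sum() + np.log(detA) + quad))

    def fit(self, maxiter: int = 2000) -> BivariateGREMLResults:
        # perfectly collinear traits make the 2x2 model singular (the
        # difference component has zero variance and the likelihood is
        # unbounded); reduce to the univariate model with rg = +/-1.
        r12 = np.corrcoef(self.Y[:, 0], self.Y[:, 1])[0, 1]
        if abs(r12) > 1 - 1e-10:
            uni = GREML.from_rotation(self.d, self.Y[:, 0], self.x).fit()
            sgn = np.sign(r12)
            ratio = np.std(self.Y[:, 1]) / max(np.std(self.Y[:, 0]), 1e-300)
            Vg = np.array([[uni.vg, sgn * uni.vg * ratio],
                           [sgn * uni.vg * ratio, uni.vg * ratio ** 2]])
            Ve = np.array([[uni.ve, sgn * uni.ve * ratio],
                           [sgn * uni.ve * ratio, uni.ve * ratio ** 2]])
            return BivariateGREMLResults(
                vg=Vg, ve=Ve, rg=float(sgn), h2=(uni.h2, uni.h2),
                loglik=float("inf"), converged=True, clipped=False, n=self.n)
        # start from an equal split of each trait's variance into Vg and Ve
        v1 = max(self.Y[:, 0].var(ddof=1), 1e-8)
        v2 = max(self.Y[:, 1].var(ddof=1), 1e-8)
        base = np.array([0.5 * np.log(v1 / 2), 0.0, 0.5 * np.log(v2 / 2),
                         0.5 * np.log(v1 / 2), 0.0, 0.5 * np.log(v2 / 2)])
        starts = [base, base + 0.3, base - 0.3]
        best = None
        for s in starts:
            res = optimize.minimize(lambda t: -self.loglik(t), s,
                                    method="Nelder-Mead",
                                    options={"maxiter": maxiter, "fatol": 1e-9,
                                             "xatol": 1e-7})
            if best is None or res.fun < best.fun:
                best = res
        Vg, Ve = self._covs(best.x)
        denom = np.sqrt(Vg[0, 0] * Vg[1, 1])
        tiny = denom < 1e-8 * np.sqrt((Vg[0, 0] + Ve[0, 0]) * (Vg[1, 1] + Ve[1, 1]))
        rg = float("nan") if tiny else Vg[0, 1] / denom
        clipped = False
        if np.isfinite(rg) and abs(rg) > 1:
            rg = float(np.clip(rg, -1, 1))
            clipped = True
        h2 = (Vg[0, 0] / (Vg[0, 0] + Ve[0, 0]), Vg[1, 1] / (Vg[1, 1] + Ve[1, 1]))
        return BivariateGREMLResults(
            vg=Vg, ve=Ve, rg=rg, h2=h2, loglik=float(-best.fun),
            converged=bool(best.success) and not tiny, clipped=clipped, n=self.n,
        )


def greml_bivariate(y1, y2, grm: Grm, lines=None) -> BivariateGREMLResults:
    return BivariateGREML(y1, y2, grm, lines=lines).fit()


# ---------------------------------------------------------------------------
# averaging across trials and element grouping
# ---------------------------------------------------------------------------

@dataclass
class ElementGrouping:
    avg_rg: pd.DataFrame
    within_env_avg: pd.Series
    groups: dict                 # element -> 1 or 2
    overrides: dict

    @property
    def group1(self):
        return [e for e, g in self.groups.items() if g == 1]

    @property
    def group2(self):
        return [e for e, g in self.groups.items() if g == 2]


def average_rg(estimates: pd.DataFrame, mode: str = "between_element"):
    """Average genetic-correlation estimates across field trials.

    ``estimates`` columns: element_a, element_b, env_a, env_b, rg, converged.
    mode ``within_element``: mean rg of the same element across environment
    pairs (one value per element). mode ``between_element``: mean over
    trials of the rg between two different elements (a symmetric matrix).
    Non-converged rows are excluded.
    """
    if len(estimates) == 0:
        raise ValueError("no genetic-correlation estimates supplied")
    df = estimates[estimates.get("converged", True).astype(bool)].copy()
    if mode == "within_element":
        same = df[df["element_a"] == df["element_b"]]
        return same.groupby("element_a")["rg"].mean().rename("within_env_avg")
    if mode == "between_element":
        diff = df[df["element_a"] != df["element_b"]]
        elements = sorted(set(df["element_a"]) | set(df["element_b"]))
        mat = pd.DataFrame(np.eye(len(elements)), index=elements, columns=elements)
        acc = {}
        for _, row in diff.iterrows():
            key = tuple(sorted((row["element_a"], row["element_b"])))
            acc.setdefault(key, []).append(row["rg"])
        for (a, b), vals in acc.items():
            mat.loc[a, b] = mat.loc[b, a] = float(np.mean(vals))
        return mat
    raise ValueError("mode must be 'within_element' or 'between_element'")


def group_elements(avg_rg: pd.DataFrame, k: int = 2,
                   overrides: dict | None = None) -> ElementGrouping:
    """Cluster elements on distance 1 - rg with average linkage.

    ``overrides`` maps element -> group id (1 or 2) and is applied after
    clustering (recorded), reproducing manual reassignments such as moving
    a weakly-correlated element into the second group. Cluster labels are
    normalised so group 1 contains the first element not overridden.
    """
    elements = list(avg_rg.index)
    if k > len(elements):
        raise ValueError("more clusters requested than elements")
    M = avg_rg.to_numpy(dtype=float)
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("average-rg matrix must be symmetric")
    D = 1.0 - M
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # deterministic relabelling: first element's cluster becomes group 1
    remap, nxt = {}, 1
    for lab in labels:
        if lab not in remap:
            remap[lab] = nxt
            nxt += 1
    groups = {e: remap[lab] for e, lab in zip(elements, labels)}
    overrides = dict(overrides or {})
    for e, g in overrides.items():
        if e not in groups:
            raise KeyError(f"override for unknown element {e!r}")
        groups[e] = int(g)
    within = pd.Series(np.nan, index=elements, name="within_env_avg")
    return ElementGrouping(avg_rg=avg_rg.copy(), within_env_avg=within,
                           groups=groups, overrides=overrides)
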