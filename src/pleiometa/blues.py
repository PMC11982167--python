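"""Best linear unbiased estimates of line values from field trials.

Each environment x element trial is analysed with the mixed model

    y = mu + X l + Z_row u_row + Z_col u_col + Z_rep u_rep + e,

where the line effects ``l`` are fixed (so their estimates are BLUEs) and
the field-design terms — row, column and replicate — are independent random
effects with their own variance components, estimated by REML. This
captures smooth field trends through row/column effects; no autoregressive
residual structure is fitted.

The model is parameterised through variance ratios gamma_f = var_f / var_e;
the residual variance is profiled out, and the three ratios are optimised
by a derivative-free Nelder-Mead search on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .datatypes import BLUE_COLUMNS

__all__ = ["TrialBLUEModel", "TrialBLUEResults", "fit_trial", "blues_all"]

_RANDOM_TERMS = ("row", "col", "rep")


def _indicator(values: np.ndarray) -> np.ndarray:
    levels, inv = np.unique(values, return_inverse=True)
    Z = np.zeros((values.size, levels.size))
    Z[np.arange(values.size), inv] = 1.0
    return Z


@dataclass
class TrialBLUEResults:
    """REML fit of one trial: variance components, BLUEs and diagnostics."""

    env: str
    element: str
    var_components: dict          # var_row, var_col, var_rep, var_resid
    loglik_reml: float
    converged: bool
    dropped_terms: list
    blues: pd.DataFrame           # line_id, blue, se
    n_plots: int

    def summary(self) -> str:
        vc = self.var_components
        lines = [
            f"Trial BLUE fit: env={self.env} element={self.element} "
            f"(n_plots={self.n_plots}, lines={len(self.blues)})",
            "  variance components:",
        ]
        for k in ("var_row", "var_col", "var_rep", "var_resid"):
            lines.append(f"    {k:10s} {vc[k]:.6g}")
        lines.append(f"  REML log-likelihood: {self.loglik_reml:.4f}  "
                     f"converged={self.converged}")
        if self.dropped_terms:
            lines.append(f"  dropped random terms: {', '.join(self.dropped_terms)}")
        return "\n".join(lines)


class TrialBLUEModel:
    """Mixed model for one env x element slice of a plot table.

    Parameters
    ----------
    plots
        DataFrame with columns row, col, rep, line_id, value (a single
        environment and element).
    """

    def __init__(self, plots: pd.DataFrame, env: str = "", element: str = ""):
        self.env = env
        self.element = element
        plots = plots.reset_index(drop=True)
        self.y = plots["value"].to_numpy(dtype=float)
        self.line_levels, line_inv = np.unique(plots["line_id"].to_numpy(), return_inverse=True)
        if self.line_levels.size < 2:
            raise ValueError("need at least 2 lines to estimate BLUEs")
        n = self.y.size
        self.X = np.zeros((n, self.line_levels.size))
        self.X[np.arange(n), line_inv] = 1.0
        # random-effect kernels; terms with < 2 levels carry no variance
        self.kernels = {}
        self.dropped = []
        for term in _RANDOM_TERMS:
            vals = plots[term].to_numpy()
            if np.unique(vals).size < 2:
                self.dropped.append(term)
                continue
            Z = _indicator(vals)
            self.kernels[term] = Z @ Z.T
        self.n = n

    # -- REML machinery --------------------------------------------------
    def _reml_loglik(self, gammas: np.ndarray):
        """Profiled REML log-likelihood at variance ratios ``gammas``.

        Returns (loglik, sigma_e2, beta_hat, cov_unscaled) where
        cov(beta) = sigma_e2 * cov_unscaled.
        """
        V = np.eye(self.n)
        for g, K in zip(gammas, self.kernels.values()):
            V += g * K
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return -np.inf, np.nan, None, None
        logdet_V = 2.0 * np.log(np.diag(L)).sum()
        Vi_y = np.linalg.solve(V, self.y)
        Vi_X = np.linalg.solve(V, self.X)
        XtViX = self.X.T @ Vi_X
        XtViy = self.X.T @ Vi_y
        try:
            C = np.linalg.cholesky(XtViX)
            beta = np.linalg.solve(XtViX, XtViy)
            cov_unscaled = np.linalg.inv(XtViX)
            logdet_XtViX = 2.0 * np.log(np.diag(C)).sum()
        except np.linalg.LinAlgError:
            beta = np.linalg.pinv(XtViX) @ XtViy
            cov_unscaled = np.linalg.pinv(XtViX)
            w = np.linalg.eigvalsh(XtViX)
            logdet_XtViX = np.log(w[w > 1e-10 * max(w.max(), 1)]).sum()
        p = self.X.shape[1]
        dof = self.n - p
        resid = self.y - self.X @ beta
        quad = resid @ np.linalg.solve(V, resid)
        if dof <= 0 or quad <= 0:
            # saturated model: no residual information
            return 0.0, 0.0, beta, cov_unscaled
        sigma2 = quad / dof
        ll = -0.5 * (dof * (np.log(2 * np.pi * sigma2) + 1.0)
                     + logdet_V + logdet_XtViX)
        return ll, sigma2, beta, cov_unscaled

    def fit(self, maxiter: int = 500, tol: float = 1e-8) -> TrialBLUEResults:
        k = len(self.kernels)
        converged = True
        if k == 0 or self.n == self.X.shape[1]:
            theta = np.full(k, -np.inf)
            gam = np.zeros(k)
            ll, sigma2, beta, cov = self._reml_loglik(gam)
        else:
            def neg(theta):
                ll, *_ = self._reml_loglik(np.exp(np.clip(theta, -30, 10)))
                return -ll

            best = None
            for start in (np.full(k, -2.0), np.full(k, 0.0)):
                res = optimize.minimize(neg, start, method="Nelder-Mead",
                                        options={"maxiter": maxiter,
                                                 "fatol": tol, "xatol": 1e-6})
                if best is None or res.fun < best.fun:
                    best = res
            converged = bool(best.success) or best.fun < neg(np.full(k, -2.0)) + 1e-6
            gam = np.exp(np.clip(best.x, -30, 10))
            gam[gam < 1e-8] = 0.0
            ll, sigma2, beta, cov = self._reml_loglik(gam)

        vc = {"var_row": 0.0, "var_col": 0.0, "var_rep": 0.0,
              "var_resid": float(sigma2)}
        for term, g in zip(self.kernels.keys(), gam):
            vc[f"var_{term}"] = float(g * sigma2)
        se = np.sqrt(np.clip(np.diag(cov), 0, None) * sigma2) if sigma2 > 0 \
            else np.full(beta.size, np.nan)
        blues = pd.DataFrame({"line_id": self.line_levels, "blue": beta, "se": se})
        return TrialBLUEResults(
            env=self.env, element=self.element, var_components=vc,
            loglik_reml=float(ll), converged=converged,
            dropped_terms=list(self.dropped), blues=blues, n_plots=self.n,
        )


def fit_trial(plots: pd.DataFrame, env: str = "", element: str = "") -> TrialBLUEResults:
    """Fit one trial (single env x element) and return BLUEs + components."""
    return TrialBLUEModel(plots, env=env, element=element).fit()


def blues_all(plots: pd.DataFrame, verbose: bool = False):
    """Fit every (env, element) trial in a plot table.

    Returns (blue_table, trial_fits): the BLUE table with columns
    ``env, element, line_id, blue, se`` and a DataFrame of per-trial
    variance components.
    """
    blue_rows, fit_rows = [], []
    for (env, element), grp in plots.groupby(["env", "element"], sort=True):
        if grp["value"].notna().sum() == 0:
            continue
        res = fit_trial(grp, env=env, element=element)
        b = res.blues.copy()
        b.insert(0, "element", element)
        b.insert(0, "env", env)
        blue_rows.append(b)
        fit_rows.append({"env": env, "element": element, **res.var_components,
                         "loglik_reml": res.loglik_reml,
                         "converged": res.converged, "n_plots": res.n_plots})
        if verbose:
            print(res.summary())
    if not blue_rows:
        raise ValueError("no (env, element) pair has data")
    blue_table = pd.concat(blue_rows, ignore_index=True)[BLUE_COLUMNS]
    return blue_table, pd.DataFrame(fit_rows)
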