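"""Recursive path-model (SEM) estimation with fit indices.

The causal structure selected by DirectLiNGAM is re-fit as an observed-
variable path model by maximum likelihood on the sample covariance of
z-scored data.  For a recursive model with independent disturbances the
ML standardized path estimates coincide with per-equation OLS standardized
coefficients; the ML machinery additionally provides standard errors
(inverse expected information), z-tests per path, the likelihood-ratio
chi-square against the saturated model, and the usual goodness-of-fit
indices (CFI, TLI, RMSEA, SRMR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = ["PathModelSpec", "SemFit", "fit_path_model", "fit_indices"]


@dataclass(frozen=True)
class PathModelSpec:
    """Directed acyclic path model over observed variables."""

    variables: tuple[str, ...]
    directed_edges: tuple[tuple[str, str], ...]  # (cause, effect)

    def __init__(self, variables, directed_edges):
        object.__setattr__(self, "variables", tuple(variables))
        object.__setattr__(
            self, "directed_edges", tuple((str(a), str(b)) for a, b in directed_edges)
        )
        known = set(self.variables)
        for a, b in self.directed_edges:
            if a not in known or b not in known:
                raise ValueError(f"edge ({a}, {b}) references unknown variable")
            if a == b:
                raise ValueError("self-loops are not allowed")
        if len(set(self.directed_edges)) != len(self.directed_edges):
            raise ValueError("duplicate edge in specification")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # Kahn's algorithm
        indeg = {v: 0 for v in self.variables}
        for _, b in self.directed_edges:
            indeg[b] += 1
        queue = [v for v, d in indeg.items() if d == 0]
        seen = 0
        while queue:
            v = queue.pop()
            seen += 1
            for a, b in self.directed_edges:
                if a == v:
                    indeg[b] -= 1
                    if indeg[b] == 0:
                        queue.append(b)
        if seen != len(self.variables):
            raise ValueError("edge set contains a cycle")

    @property
    def endogenous(self) -> list[str]:
        return [v for v in self.variables if any(b == v for _, b in self.directed_edges)]

    @property
    def exogenous(self) -> list[str]:
        endo = set(self.endogenous)
        return [v for v in self.variables if v not in endo]

    def parents(self, v: str) -> list[str]:
        return [a for a, b in self.directed_edges if b == v]


@dataclass
class SemFit:
    """ML path-model fit: standardized paths, tests and fit indices."""

    paths: pd.DataFrame  # cause, effect, estimate, se, z, p
    chi_square: float
    df: int
    fit_indices: dict[str, float]
    implied_cov: np.ndarray
    sample_cov: np.ndarray
    n: int
    converged: bool


def _fml(sample: np.ndarray, implied: np.ndarray) -> float:
    """ML discrepancy F = log|Sigma| + tr(S Sigma^-1) - log|S| - p."""
    p = sample.shape[0]
    sign_i, logdet_i = np.linalg.slogdet(implied)
    sign_s, logdet_s = np.linalg.slogdet(sample)
    if sign_i <= 0 or sign_s <= 0:
        return np.inf
    return float(
        logdet_i + np.trace(sample @ np.linalg.inv(implied)) - logdet_s - p
    )


def fit_indices(
    sample_cov: np.ndarray,
    implied_cov: np.ndarray,
    n: int,
    df: int,
    df_baseline: int,
    chi_baseline: float,
) -> dict[str, float]:
    """Chi-square and CFI/TLI/RMSEA/SRMR from sample and implied covariances.

    Saturated convention: with ``df == 0`` RMSEA is reported as 0 and CFI
    as 1.
    """
    sample_cov = np.asarray(sample_cov, dtype=float)
    implied_cov = np.asarray(implied_cov, dtype=float)
    if np.any(np.linalg.eigvalsh(sample_cov) <= 0) or np.any(
        np.linalg.eigvalsh(implied_cov) <= 0
    ):
        raise ValueError("covariance matrices must be positive definite")
    chi = (n - 1) * _fml(sample_cov, implied_cov)

    d = np.sqrt(np.diag(sample_cov))
    resid = (sample_cov - implied_cov) / np.outer(d, d)
    tri = resid[np.tril_indices_from(resid)]
    srmr = float(np.sqrt(np.mean(tri**2)))

    if df == 0:
        cfi, tli, rmsea = 1.0, 1.0, 0.0
    else:
        num = max(chi - df, 0.0)
        denom = max(chi_baseline - df_baseline, num, 1e-300)
        cfi = 1.0 - num / denom
        ratio_b = chi_baseline / df_baseline if df_baseline > 0 else np.inf
        ratio_m = chi / df
        tli = (ratio_b - ratio_m) / (ratio_b - 1.0) if ratio_b > 1.0 else 1.0
        rmsea = float(np.sqrt(max(chi - df, 0.0) / (df * (n - 1))))
    return {
        "chi_square": float(chi),
        "cfi": float(cfi),
        "tli": float(tli),
        "rmsea": float(rmsea),
        "srmr": srmr,
    }


def _implied_cov(
    spec: PathModelSpec, beta: dict[tuple[str, str], float], psi: np.ndarray
) -> np.ndarray:
    p = len(spec.variables)
    idx = {v: i for i, v in enumerate(spec.variables)}
    bmat = np.zeros((p, p))
    for (a, b), val in beta.items():
        bmat[idx[b], idx[a]] = val
    inv = np.linalg.inv(np.eye(p) - bmat)
    return inv @ psi @ inv.T


def _pack_params(spec: PathModelSpec):
    """Parameter layout: edge coefficients, exogenous (co)variances, disturbance variances."""
    exo = spec.exogenous
    entries: list[tuple[str, object]] = [("edge", e) for e in spec.directed_edges]
    for i, v in enumerate(exo):
        entries.append(("exo_var", v))
        for w in exo[i + 1 :]:
            entries.append(("exo_cov", (v, w)))
    for v in spec.endogenous:
        entries.append(("dist_var", v))
    return entries


def _theta_to_cov(theta: np.ndarray, spec: PathModelSpec, entries) -> np.ndarray:
    p = len(spec.variables)
    idx = {v: i for i, v in enumerate(spec.variables)}
    beta: dict[tuple[str, str], float] = {}
    psi = np.zeros((p, p))
    for val, (kind, key) in zip(theta, entries):
        if kind == "edge":
            beta[key] = val
        elif kind == "exo_var" or kind == "dist_var":
            psi[idx[key], idx[key]] = val
        else:
            i, j = idx[key[0]], idx[key[1]]
            psi[i, j] = psi[j, i] = val
    return _implied_cov(spec, beta, psi)


def _numerical_hessian(f, x0: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    k = len(x0)
    h = np.zeros((k, k))
    f0 = f(x0)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = eps
            ej[j] = eps
            fpp = f(x0 + ei + ej)
            fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej)
            fmm = f(x0 - ei - ej)
            h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps**2)
    del f0
    return h


def fit_path_model(
    x: np.ndarray | pd.DataFrame, spec: PathModelSpec
) -> SemFit:
    """ML fit of a recursive path model on z-scored data.

    Raises on cyclic specifications (via :class:`PathModelSpec`), singular
    covariance, or too few observations for the parameter count.
    """
    if isinstance(x, pd.DataFrame):
        missing = [v for v in spec.variables if v not in x.columns]
        if missing:
            raise ValueError(f"data is missing variables {missing}")
        x = x.loc[:, list(spec.variables)].to_numpy(dtype=float)
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != len(spec.variables):
        raise ValueError("data shape does not match the model variables")
    n, p = x.shape
    entries = _pack_params(spec)
    if n <= len(entries):
        raise ValueError("need more observations than free parameters")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant variable in path model data")
    xz = (x - x.mean(axis=0)) / sd
    s = np.cov(xz, rowvar=False, ddof=1)
    if np.linalg.matrix_rank(s) < p:
        raise ValueError("singular sample covariance")

    idx = {v: i for i, v in enumerate(spec.variables)}

    # OLS start (exact ML optimum for recursive models with independent disturbances)
    theta0 = np.zeros(len(entries))
    resid_var: dict[str, float] = {}
    for v in spec.endogenous:
        pars = spec.parents(v)
        xp = xz[:, [idx[a] for a in pars]]
        coef, *_ = np.linalg.lstsq(xp, xz[:, idx[v]], rcond=None)
        res = xz[:, idx[v]] - xp @ coef
        resid_var[v] = float(res @ res) / (n - 1)
        for a, c in zip(pars, coef):
            theta0[entries.index(("edge", (a, v)))] = c
    for k, (kind, key) in enumerate(entries):
        if kind == "exo_var":
            theta0[k] = s[idx[key], idx[key]]
        elif kind == "exo_cov":
            theta0[k] = s[idx[key[0]], idx[key[1]]]
        elif kind == "dist_var":
            theta0[k] = resid_var[key]

    def objective(theta: np.ndarray) -> float:
        return _fml(s, _theta_to_cov(theta, spec, entries))

    res = minimize(objective, theta0, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    theta = res.x if res.fun <= objective(theta0) else theta0
    converged = bool(res.success) or objective(theta0) <= res.fun

    implied = _theta_to_cov(theta, spec, entries)
    fmin = objective(theta)
    chi = (n - 1) * fmin
    n_moments = p * (p + 1) // 2
    df = n_moments - len(entries)

    # standard errors from the expected information: cov(theta) = 2/(n-1) H^-1
    hess = _numerical_hessian(objective, theta)
    try:
        cov_theta = 2.0 / (n - 1) * np.linalg.inv(hess)
        se_all = np.sqrt(np.clip(np.diag(cov_theta), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se_all = np.full(len(entries), np.nan)

    # implied SDs standardize the path estimates (inputs are z-scored, so
    # these are ~1; kept for exactness)
    isd = np.sqrt(np.diag(implied))
    rows = []
    for k, (kind, key) in enumerate(entries):
        if kind != "edge":
            continue
        a, b = key
        est = float(theta[k]) * isd[idx[a]] / isd[idx[b]]
        se = float(se_all[k])
        z = est / se if se > 0 else np.nan
        rows.append(
            {
                "cause": a,
                "effect": b,
                "estimate": est,
                "se": se,
                "z": z,
                "p": float(2 * norm.sf(abs(z))) if np.isfinite(z) else np.nan,
            }
        )

    # independence baseline for the incremental indices
    baseline_implied = np.diag(np.diag(s))
    df_baseline = p * (p - 1) // 2
    chi_baseline = (n - 1) * _fml(s, baseline_implied)
    indices = fit_indices(s, implied, n, df, df_baseline, chi_baseline)

    return SemFit(
        paths=pd.DataFrame(rows),
        chi_square=float(chi),
        df=int(df),
        fit_indices=indices,
        implied_cov=implied,
        sample_cov=s,
        n=n,
        converged=converged,
    )
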