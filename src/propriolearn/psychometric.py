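"""Psychometric-function fitting for the 2AFC proprioceptive judgment task.

Eighty trials present a reference elbow angle (30 deg or 50 deg) followed by
a test angle deviating by +/-2, 4, 6 or 8 deg; the participant reports
whether the test felt larger (more flexed) or smaller.  The proportion of
"larger" responses as a function of the signed deviation is fitted with a
cumulative Gaussian Phi((delta - mu) / sigma) by maximum likelihood, and
acuity is summarised by the just-noticeable difference

    JND = (x75 - x25) / 2 = sigma * Phi^-1(0.75),

half the stimulus distance between the 25% and 75% points of the fitted
curve.  A low JND means high acuity.

The two reference angles are pooled before fitting (the psychometric curve
is expressed purely as a function of the deviation); per-reference cell
tables are available for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = [
    "JudgmentTrial",
    "PsychometricFit",
    "aggregate_2afc",
    "fit_cumulative_gaussian",
    "jnd_from_fit",
    "fit_judgment_table",
    "SIGMA_BOUNDS",
]

#: slope bounds (degrees); fits pinned at a bound are flagged unconverged
SIGMA_BOUNDS = (0.1, 50.0)
_Z75 = float(norm.ppf(0.75))


@dataclass(frozen=True)
class JudgmentTrial:
    """One 2AFC trial: reference angle, signed deviation, and response."""

    reference: float
    deviation: float
    response: str  # "larger" | "smaller"

    def __post_init__(self) -> None:
        if self.response not in ("larger", "smaller"):
            raise ValueError(f"unknown response {self.response!r}")


@dataclass
class PsychometricFit:
    """Fitted cumulative Gaussian and the derived JND."""

    mu: float
    sigma: float
    jnd: float
    cells: pd.DataFrame  # columns: deviation, n, k, proportion
    converged: bool


def _to_frame(trials: Iterable[JudgmentTrial] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        df = trials
    else:
        df = pd.DataFrame(
            [
                {"reference": t.reference, "deviation": t.deviation, "response": t.response}
                for t in trials
            ]
        )
    if len(df) == 0:
        raise ValueError("no judgment trials supplied")
    return df


def aggregate_2afc(
    trials: Iterable[JudgmentTrial] | pd.DataFrame,
    by_reference: bool = False,
) -> pd.DataFrame:
    """Pool trials into per-deviation cells of "larger"-response counts.

    Returns a table with one row per deviation (pooled over the two
    reference angles unless ``by_reference``), with columns ``n`` (trials),
    ``k`` ("larger" responses) and ``proportion``.
    """
    df = _to_frame(trials)
    keys = ["reference", "deviation"] if by_reference else ["deviation"]
    grouped = df.groupby(keys, sort=True).agg(
        n=("response", "size"),
        k=("response", lambda s: int((s == "larger").sum())),
    )
    cells = grouped.reset_index()
    cells["proportion"] = cells["k"] / cells["n"]
    return cells


def _nll(params: np.ndarray, dev: np.ndarray, k: np.ndarray, n: np.ndarray) -> float:
    mu, sigma = params
    p = norm.cdf((dev - mu) / sigma)
    p = np.clip(p, 1e-10, 1.0 - 1e-10)
    return float(-(k * np.log(p) + (n - k) * np.log(1.0 - p)).sum())


def fit_cumulative_gaussian(cells: pd.DataFrame) -> PsychometricFit:
    """Maximum-likelihood Bernoulli fit of P(larger | deviation).

    Degenerate sessions (e.g. identical responses everywhere, which drive
    the slope to a bound) are reported with ``converged=False`` rather than
    raised.  The fit is deterministic: no randomness is involved.
    """
    required = {"deviation", "n", "k"}
    if not required.issubset(cells.columns):
        raise ValueError(f"cell table must have columns {sorted(required)}")
    cells = cells[cells["n"] > 0]
    if cells["deviation"].nunique() < 2:
        raise ValueError("need at least two distinct deviations with trials")

    dev = cells["deviation"].to_numpy(dtype=float)
    k = cells["k"].to_numpy(dtype=float)
    n = cells["n"].to_numpy(dtype=float)

    # moment-based start: mean/SD of the implied threshold distribution
    props = np.clip(k / n, 0.05, 0.95)
    z = norm.ppf(props)
    slope = np.polyfit(dev, z, 1)
    sigma0 = float(np.clip(1.0 / max(slope[0], 1e-3), *SIGMA_BOUNDS))
    mu0 = float(np.clip(-slope[1] * sigma0, -30.0, 30.0))

    res = minimize(
        _nll,
        x0=np.array([mu0, sigma0]),
        args=(dev, k, n),
        method="L-BFGS-B",
        bounds=[(-50.0, 50.0), SIGMA_BOUNDS],
    )
    mu, sigma = float(res.x[0]), float(res.x[1])
    at_bound = (
        sigma <= SIGMA_BOUNDS[0] + 1e-8 or sigma >= SIGMA_BOUNDS[1] - 1e-8
    )
    converged = bool(res.success) and not at_bound

    out_cells = cells.copy()
    out_cells["proportion"] = out_cells["k"] / out_cells["n"]
    fit = PsychometricFit(
        mu=mu, sigma=sigma, jnd=sigma * _Z75, cells=out_cells, converged=converged
    )
    return fit


def jnd_from_fit(fit: PsychometricFit) -> float:
    """JND = (x75 - x25)/2 from the fitted curve (equals sigma * 0.6745)."""
    x75 = fit.mu + fit.sigma * _Z75
    x25 = fit.mu - fit.sigma * _Z75
    return (x75 - x25) / 2.0


def fit_judgment_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Fit every participant in a long-format ``judgment_trials`` table."""
    rows = []
    for pid, group in trials.groupby("participant_id", sort=True):
        fit = fit_cumulative_gaussian(aggregate_2afc(group))
        rows.append(
            {
                "participant_id": pid,
                "mu": fit.mu,
                "sigma": fit.sigma,
                "jnd": fit.jnd,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
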