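"""Trajectory reproduction scoring.

Similarity between a target elbow-angle trajectory and an actively
reproduced one is scored by the *peak normalized cross-correlation*: the
Pearson correlation between the two series is computed at every integer
sample lag within a window, using only the overlapping segment at each lag
(both segments re-centred and re-scaled per lag), and the maximum is taken.
This deliberately ignores the onset-time difference between the two
movements.  A complementary zero-lag RMSE, which *does* penalise temporal
misalignment, is provided as a secondary score.

The learning-efficiency measure is the improvement index: mean peak
correlation over the post-learning reproductions minus the mean over the
pre-learning reproductions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Trajectory",
    "ReproductionScore",
    "xcorr_peak",
    "rmse_at_zero_lag",
    "improvement_index",
    "score_phase",
]

#: variance below which a segment is treated as constant (correlation undefined)
_VAR_EPS = 1e-12


@dataclass(frozen=True)
class Trajectory:
    """A uniformly sampled joint-angle time series.

    Parameters
    ----------
    samples : numpy.ndarray
        Angle values in degrees, one per sample.
    rate : float
        Sampling rate in Hz (250 Hz for the elbow encoder data this
        package emulates).
    """

    samples: np.ndarray
    rate: float = 250.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1:
            raise ValueError("trajectory samples must be one-dimensional")
        if arr.size == 0:
            raise ValueError("trajectory must contain at least one sample")
        if not np.all(np.isfinite(arr)):
            raise ValueError("trajectory samples must be finite")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "samples", arr)

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return len(self.samples) / self.rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(len(self.samples)) / self.rate

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class ReproductionScore:
    """Per-phase reproduction similarity and the improvement index.

    ``improvement`` is ``mean(post peak r) - mean(pre peak r)``; positive
    values mean the reproductions became more similar to the target after
    the guidance block.
    """

    pre_peak_r: list[float] = field(default_factory=list)
    post_peak_r: list[float] = field(default_factory=list)
    pre_lag: list[float] = field(default_factory=list)
    post_lag: list[float] = field(default_factory=list)
    pre_rmse: list[float] = field(default_factory=list)
    post_rmse: list[float] = field(default_factory=list)

    @property
    def pre_mean_r(self) -> float:
        return float(np.mean(self.pre_peak_r))

    @property
    def post_mean_r(self) -> float:
        return float(np.mean(self.post_peak_r))

    @property
    def pre_mean_rmse(self) -> float:
        return float(np.mean(self.pre_rmse))

    @property
    def post_mean_rmse(self) -> float:
        return float(np.mean(self.post_rmse))

    @property
    def improvement(self) -> float:
        return improvement_index(self.pre_peak_r, self.post_peak_r)

    @property
    def rmse_improvement(self) -> float:
        """Pre minus post RMSE: positive when error decreased."""
        return self.pre_mean_rmse - self.post_mean_rmse


def _overlap_stats(a: np.ndarray, b: np.ndarray, max_lag_samples: int):
    """Sums needed for per-lag Pearson correlations over overlap windows.

    For lag ``l`` the overlap pairs ``a[i + l]`` with ``b[i]``; positive lags
    mean the feature in ``a`` occurs *later* than in ``b``.
    """
    na, nb = len(a), len(b)
    # full cross products: c[k] pairs a[j] with b[j - (k - (nb - 1))]
    cross = np.correlate(a, b, mode="full")
    lags_full = np.arange(-(nb - 1), na)

    ca = np.concatenate(([0.0], np.cumsum(a)))
    ca2 = np.concatenate(([0.0], np.cumsum(a * a)))
    cb = np.concatenate(([0.0], np.cumsum(b)))
    cb2 = np.concatenate(([0.0], np.cumsum(b * b)))

    keep = np.abs(lags_full) <= max_lag_samples
    out = []
    for lag, sab in zip(lags_full[keep], cross[keep]):
        # overlap indices in a: [max(0, lag), min(na, nb + lag))
        a_lo, a_hi = max(0, lag), min(na, nb + lag)
        m = a_hi - a_lo
        if m < 2:
            continue
        b_lo, b_hi = a_lo - lag, a_hi - lag
        sa, sa2 = ca[a_hi] - ca[a_lo], ca2[a_hi] - ca2[a_lo]
        sb, sb2 = cb[b_hi] - cb[b_lo], cb2[b_hi] - cb2[b_lo]
        out.append((int(lag), m, sa, sa2, sb, sb2, sab))
    return out


def xcorr_peak(
    a: Trajectory, b: Trajectory, max_lag: float = 2.5
) -> tuple[float, float]:
    """Peak normalized cross-correlation between two trajectories.

    The Pearson correlation is evaluated at every integer-sample lag in
    ``[-max_lag, +max_lag]`` seconds over the overlapping segment only
    (re-centred and re-scaled per lag), and the maximum is returned together
    with its lag in seconds.  Ties are broken toward the smallest ``|lag|``.
    Lags at which either overlapping segment is constant are skipped.

    Returns
    -------
    (peak_r, lag_seconds)
        ``lag_seconds > 0`` means the matching feature occurs later in
        ``a`` than in ``b``.
    """
    if a.rate != b.rate:
        raise ValueError("trajectories must share a sampling rate")
    if max_lag < 0:
        raise ValueError("max_lag must be non-negative")
    max_lag_samples = int(round(max_lag * a.rate))

    best_r, best_lag = -np.inf, None
    for lag, m, sa, sa2, sb, sb2, sab in _overlap_stats(
        a.samples, b.samples, max_lag_samples
    ):
        var_a = sa2 / m - (sa / m) ** 2
        var_b = sb2 / m - (sb / m) ** 2
        if var_a <= _VAR_EPS or var_b <= _VAR_EPS:
            continue
        cov = sab / m - (sa / m) * (sb / m)
        r = cov / np.sqrt(var_a * var_b)
        r = float(np.clip(r, -1.0, 1.0))
        if r > best_r + 1e-12 or (
            abs(r - best_r) <= 1e-12
            and best_lag is not None
            and abs(lag) < abs(best_lag)
        ):
            best_r, best_lag = r, lag
    if best_lag is None:
        raise ValueError(
            "correlation undefined at every admissible lag "
            "(constant overlap segments)"
        )
    return best_r, best_lag / a.rate


def rmse_at_zero_lag(a: Trajectory, b: Trajectory) -> float:
    """Root-mean-square error with no temporal alignment."""
    if len(a) != len(b):
        raise ValueError("trajectories must have equal length for zero-lag RMSE")
    d = a.samples - b.samples
    return float(np.sqrt(np.mean(d * d)))


def improvement_index(pre: list[float], post: list[float]) -> float:
    """Mean post-phase peak correlation minus mean pre-phase peak correlation."""
    if len(pre) == 0 or len(post) == 0:
        raise ValueError("pre and post score lists must be nonempty")
    return float(np.mean(post) - np.mean(pre))


def score_phase(
    target: Trajectory,
    reproductions: list[Trajectory],
    max_lag: float = 2.5,
) -> tuple[list[float], list[float], list[float]]:
    """Score one phase's reproductions against the target.

    Returns per-trial lists ``(peak_r, lag_seconds, rmse)``.
    """
    rs, lags, rmses = [], [], []
    for rep in reproductions:
        r, lag = xcorr_peak(target, rep, max_lag=max_lag)
        rs.append(r)
        lags.append(lag)
        rmses.append(rmse_at_zero_lag(target, rep))
    return rs, lags, rmses
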