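"""Calibrated synthetic cohort for the three proprioception tasks.

The generator emulates a cohort of participants performing (a) a 60-trial
recognition-memory task over elbow angles 8-82 deg in 2 deg steps, (b) an
80-trial 2AFC angle-judgment task with references 30/50 deg and deviations
+/-2..8 deg, and (c) a passively guided trajectory-learning task with 10-s
elbow trajectories sampled at 250 Hz (5 pre- and 5 post-learning
reproductions around 30 guidance repetitions).

Each participant carries three standardized latent traits linked by a
linear structural model with independent non-Gaussian disturbances:

    A  (acuity; higher = worse discrimination)      A = e_A
    M  (short-term memory)                          M = b_AM * A + e_M
    L  (learning efficiency)                        L = b_ML * M + b_AL * A + e_L

with defaults b_AM = -0.39, b_ML = 0.70, b_AL = 0 and uniform disturbances
scaled so every trait has unit population variance.  The traits map onto
mechanistic task parameters (perceptual noise, encoding noise,
serial-position decay, reproduction fidelity) through fixed monotone links
whose constants were calibrated once, by coarse grid search, so that the
pipeline's cohort summary statistics match the reference cohort values the
package is built around (see ``REFERENCE_COHORT_SUMMARY`` in
:mod:`propriolearn.study_pipeline` and docs/methods.md).

Randomness is organised as one independently seeded stream per participant
and per task, derived from the master seed by a counter scheme, so adding
participants to a cohort never perturbs existing ones.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .memory_scoring import MemoryTrial
from .psychometric import JudgmentTrial
from .trajectory_similarity import Trajectory

__all__ = [
    "StructuralTraitModel",
    "TraitLinkParams",
    "ParticipantProfile",
    "CohortConfig",
    "CohortData",
    "sample_traits",
    "generate_memory_session",
    "generate_judgment_session",
    "generate_target_trajectory",
    "generate_reproduction",
    "simulate_cohort",
]

_SQRT3 = math.sqrt(3.0)

# task codes for the per-participant RNG counter scheme
_STREAM_TRAITS, _STREAM_MEMORY, _STREAM_JUDGMENT, _STREAM_TRAJ = 0, 1, 2, 3
_STREAM_TARGET = (1 << 20, 7)  # cohort-level stream for the shared target


@dataclass(frozen=True)
class StructuralTraitModel:
    """Linear structural model over the latent traits (A, M, L).

    ``coeff_am`` is the acuity-to-memory path, ``coeff_ml`` the
    memory-to-learning path, and ``coeff_al`` the direct acuity-to-learning
    path (0 by default: acuity influences learning only via memory).
    Disturbances are independent, zero-mean, non-Gaussian draws from
    ``noise_family`` scaled so each trait has unit population variance.
    """

    coeff_am: float = -0.39
    coeff_ml: float = 0.70
    coeff_al: float = 0.0
    noise_family: str = "uniform"

    def __post_init__(self) -> None:
        for c in (self.coeff_am, self.coeff_ml, self.coeff_al):
            if not np.isfinite(c):
                raise ValueError("path coefficients must be finite")
        if self.noise_family not in ("uniform", "laplace", "gaussian"):
            raise ValueError(f"unknown noise family {self.noise_family!r}")

    def disturbance_variances(self) -> tuple[float, float, float]:
        """Variances of (e_A, e_M, e_L) giving unit-variance traits."""
        var_em = 1.0 - self.coeff_am**2
        struct_l = (
            self.coeff_ml**2
            + self.coeff_al**2
            + 2.0 * self.coeff_ml * self.coeff_al * self.coeff_am
        )
        var_el = 1.0 - struct_l
        if var_em <= 0 or var_el <= 0:
            raise ValueError(
                "path coefficients imply non-positive disturbance variance; "
                "traits cannot be standardized"
            )
        return 1.0, var_em, var_el


@dataclass(frozen=True)
class TraitLinkParams:
    """Fixed monotone links from latent traits to task parameters.

    These constants are the calibration surface of the generator; the
    defaults were fitted once by coarse grid search against the reference
    cohort summary statistics and are not meant to be tuned per run.
    Units are degrees unless noted.
    """

    # perceptual noise: sigma_p = exp(mu_p + s_p * A)
    sigma_p_log_mean: float = 1.44
    sigma_p_log_slope: float = 0.32
    sigma_p_range: tuple[float, float] = (0.2, 6.8)
    # encoding noise: sigma_enc = exp(mu_m - s_m * M)
    sigma_enc_log_mean: float = 1.55
    sigma_enc_log_slope: float = 0.35
    sigma_enc_range: tuple[float, float] = (0.3, 25.0)
    # serial-position decay (deg / retained item), decreasing in M so that
    # good memorizers favour older items (primacy) and poor ones recency
    decay_intercept: float = 3.5
    decay_slope_m: float = 5.0
    sigma_floor: float = 0.5
    # recognition decision radius
    match_criterion: float = 7.5
    # liberal-criterion guessing: P("present" | no trace within the
    # criterion) = logistic(g0 + g1 * M); poorer memorizers guess more
    guess_logit_intercept: float = -0.82
    guess_logit_slope: float = -0.3
    # reproduction fidelity: rho_post - rho_pre = logistic in L
    rho_pre: float = 0.42
    gap_min: float = 0.02
    gap_max: float = 0.30
    gap_steepness: float = 1.5
    rho_max: float = 0.98
    motor_noise_sd: float = 2.0


DEFAULT_LINKS = TraitLinkParams()


@dataclass(frozen=True)
class ParticipantProfile:
    """Latent traits and the mechanistic task parameters they map to."""

    id: str
    a: float
    m: float
    l: float
    sigma_p: float
    sigma_enc: float
    decay_slope: float
    match_criterion: float
    guess_rate: float
    rho_pre: float
    rho_post: float

    def __post_init__(self) -> None:
        if self.sigma_p <= 0 or self.sigma_enc <= 0:
            raise ValueError("noise SDs must be positive")
        if self.match_criterion <= 0:
            raise ValueError("match criterion must be positive")
        if not 0.0 <= self.guess_rate < 1.0:
            raise ValueError("guess rate must lie in [0, 1)")
        if not (0.0 <= self.rho_pre <= self.rho_post <= 1.0):
            raise ValueError("need 0 <= rho_pre <= rho_post <= 1")

    def position_noise_sd(self, position: int, floor: float = 0.5) -> float:
        """Encoding-noise SD for serial position 1 (oldest) .. 3 (newest)."""
        return max(floor, self.sigma_enc + self.decay_slope * (3 - position))


@dataclass(frozen=True)
class CohortConfig:
    """Task-design constants and trajectory-generator parameters."""

    n_participants: int = 21
    seed: int = 0
    # recognition-memory task
    memory_trials: int = 60
    present_trials: int = 30
    angle_min: float = 8.0
    angle_max: float = 82.0
    angle_step: float = 2.0
    min_separation: float = 10.0
    # 2AFC judgment task
    references: tuple[float, ...] = (30.0, 50.0)
    deviations: tuple[float, ...] = (-8.0, -6.0, -4.0, -2.0, 2.0, 4.0, 6.0, 8.0)
    reps_per_cell: int = 5
    # trajectory task
    duration_s: float = 10.0
    rate_hz: float = 250.0
    n_short_instruction: int = 5
    n_pre: int = 5
    n_guidance: int = 30
    n_post: int = 5
    # target-trajectory generator
    harmonics: tuple[int, int] = (2, 4)
    freq_band: tuple[float, float] = (0.1, 0.8)
    amplitude_deg: float = 38.0
    center_deg: float = 45.0
    taper_s: float = 1.0
    # a participant's distractor (default movement) is redrawn until its
    # peak normalized cross-correlation with the target falls below this,
    # so "unrelated" movements are genuinely unrelated
    distractor_max_peak_r: float = 0.3

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ValueError("participant count must be non-negative")
        if self.memory_trials <= 0 or not 0 < self.present_trials <= self.memory_trials:
            raise ValueError("invalid memory-trial counts")
        if self.duration_s <= 0 or self.rate_hz <= 0:
            raise ValueError("duration and rate must be positive")
        if len(self.angle_grid()) < 3:
            raise ValueError("angle grid too small for three memory angles")
        if self.harmonics[0] > self.harmonics[1] or self.harmonics[0] < 0:
            raise ValueError("invalid harmonic count range")

    def angle_grid(self) -> np.ndarray:
        """The admissible memory/test angles (38 values by default)."""
        n = int(round((self.angle_max - self.angle_min) / self.angle_step)) + 1
        return self.angle_min + self.angle_step * np.arange(n)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.rate_hz))


def _participant_rng(seed: int, index: int, task: int) -> np.random.Generator:
    """Independent stream for (participant index, task), stable under cohort growth."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index, task)))


def _draw_disturbance(
    rng: np.random.Generator, family: str, variance: float
) -> float:
    sd = math.sqrt(variance)
    if family == "uniform":
        return float(rng.uniform(-_SQRT3 * sd, _SQRT3 * sd))
    if family == "laplace":
        return float(rng.laplace(0.0, sd / math.sqrt(2.0)))
    return float(rng.normal(0.0, sd))


def _profile_from_traits(
    pid: str, a: float, m: float, l: float, links: TraitLinkParams
) -> ParticipantProfile:
    sigma_p = float(
        np.clip(
            math.exp(links.sigma_p_log_mean + links.sigma_p_log_slope * a),
            *links.sigma_p_range,
        )
    )
    sigma_enc = float(
        np.clip(
            math.exp(links.sigma_enc_log_mean - links.sigma_enc_log_slope * m),
            *links.sigma_enc_range,
        )
    )
    decay = links.decay_intercept - links.decay_slope_m * m
    guess = float(
        expit(links.guess_logit_intercept + links.guess_logit_slope * m)
    )
    gap = links.gap_min + (links.gap_max - links.gap_min) * float(
        expit(links.gap_steepness * l)
    )
    rho_pre = links.rho_pre
    rho_post = min(links.rho_max, rho_pre + gap)
    return ParticipantProfile(
        id=pid,
        a=a,
        m=m,
        l=l,
        sigma_p=sigma_p,
        sigma_enc=sigma_enc,
        decay_slope=decay,
        match_criterion=links.match_criterion,
        guess_rate=guess,
        rho_pre=rho_pre,
        rho_post=rho_post,
    )


def sample_traits(
    model: StructuralTraitModel,
    n: int,
    seed: int,
    links: TraitLinkParams = DEFAULT_LINKS,
) -> list[ParticipantProfile]:
    """Sample ``n`` participants' latent traits and mechanistic parameters.

    Traits follow the structural model with independent ``noise_family``
    disturbances, each trait having unit population variance.  A Gaussian
    noise family is accepted but triggers a warning: the causal direction
    of a linear model with Gaussian disturbances is not identifiable.
    """
    if n < 1:
        raise ValueError("need at least one participant")
    if model.noise_family == "gaussian":
        warnings.warn(
            "Gaussian disturbances make the structural model unidentifiable "
            "for LiNGAM-style causal discovery",
            UserWarning,
            stacklevel=2,
        )
    var_ea, var_em, var_el = model.disturbance_variances()
    profiles = []
    width = max(3, len(str(n)))
    for i in range(n):
        rng = _participant_rng(seed, i, _STREAM_TRAITS)
        e_a = _draw_disturbance(rng, model.noise_family, var_ea)
        e_m = _draw_disturbance(rng, model.noise_family, var_em)
        e_l = _draw_disturbance(rng, model.noise_family, var_el)
        a = e_a
        m = model.coeff_am * a + e_m
        l = model.coeff_ml * m + model.coeff_al * a + e_l
        profiles.append(
            _profile_from_traits(f"p{i + 1:0{width}d}", a, m, l, links)
        )
    return profiles


def _sample_separated_angles(
    rng: np.random.Generator,
    grid: np.ndarray,
    k: int,
    min_sep: float,
    max_tries: int = 2000,
) -> np.ndarray:
    """k angles from the grid, pairwise >= min_sep apart, in presentation order."""
    for _ in range(max_tries):
        angles = rng.choice(grid, size=k, replace=False)
        if np.min(np.diff(np.sort(angles))) >= min_sep:
            return angles
    raise RuntimeError(
        f"could not draw {k} angles with separation >= {min_sep} from the grid"
    )


def generate_memory_session(
    profile: ParticipantProfile,
    config: CohortConfig,
    rng: np.random.Generator,
    sigma_floor: float = DEFAULT_LINKS.sigma_floor,
) -> list[MemoryTrial]:
    """Simulate one 60-trial recognition-memory session.

    Trial structure: three memory angles pairwise >= ``min_separation``
    apart; in present trials the test angle equals one of them (balanced
    10/10/10 over serial positions); in absent trials the test angle is a
    new grid angle >= ``min_separation`` from every memorized angle.

    Responses follow a noisy stored-trace model: each memorized angle is
    stored with Gaussian noise whose SD grows (or shrinks, for
    primacy-favouring participants) with the number of subsequently
    retained items; the participant answers "present" when the test angle
    falls within ``match_criterion`` of the nearest stored trace and names
    that trace's position.  When no trace matches, the participant still
    guesses "present" with probability ``guess_rate`` (a liberal
    recognition criterion; without it the task's >= 10 deg separations
    would make realistic false-alarm rates unreachable).
    """
    grid = config.angle_grid()
    n_absent = config.memory_trials - config.present_trials
    # balanced matched positions for present trials, as equal as counts allow
    positions = [1 + (i % 3) for i in range(config.present_trials)]
    conditions = ["present"] * config.present_trials + ["absent"] * n_absent
    matched = positions + [None] * n_absent
    order = rng.permutation(config.memory_trials)

    sds = [profile.position_noise_sd(pos, floor=sigma_floor) for pos in (1, 2, 3)]
    trials = []
    for idx in order:
        condition, pos = conditions[idx], matched[idx]
        angles = _sample_separated_angles(rng, grid, 3, config.min_separation)
        if condition == "present":
            test = float(angles[pos - 1])
        else:
            far = grid[
                np.min(np.abs(grid[:, None] - angles[None, :]), axis=1)
                >= config.min_separation
            ]
            if len(far) == 0:
                raise RuntimeError("no admissible absent test angle")
            test = float(rng.choice(far))
        stored = angles + rng.normal(0.0, sds, size=3)
        dist = np.abs(test - stored)
        nearest = int(np.argmin(dist))
        if dist[nearest] < profile.match_criterion:
            response, named = "present", nearest + 1
        elif rng.uniform() < profile.guess_rate:
            # no trace matches, but the participant guesses "present",
            # naming the nearest trace (liberal recognition criterion)
            response, named = "present", nearest + 1
        else:
            response, named = "absent", None
        trials.append(
            MemoryTrial(
                angle1=float(angles[0]),
                angle2=float(angles[1]),
                angle3=float(angles[2]),
                test_angle=test,
                condition=condition,
                matched_position=pos,
                response=response,
                named_position=named,
            )
        )
    return trials


def generate_judgment_session(
    profile: ParticipantProfile,
    config: CohortConfig,
    rng: np.random.Generator,
) -> list[JudgmentTrial]:
    """Simulate one 80-trial 2AFC judgment session.

    Both the reference and the test percept carry independent perceptual
    noise of SD ``sigma_p``, so the probability of judging the test larger
    is Phi(delta / (sqrt(2) * sigma_p)) for signed deviation delta.
    """
    from scipy.stats import norm

    cells = [
        (ref, dev)
        for ref in config.references
        for dev in config.deviations
        for _ in range(config.reps_per_cell)
    ]
    order = rng.permutation(len(cells))
    trials = []
    for idx in order:
        ref, dev = cells[idx]
        p_larger = float(norm.cdf(dev / (math.sqrt(2.0) * profile.sigma_p)))
        response = "larger" if rng.uniform() < p_larger else "smaller"
        trials.append(JudgmentTrial(reference=ref, deviation=dev, response=response))
    return trials


def generate_target_trajectory(
    config: CohortConfig, rng: np.random.Generator
) -> Trajectory:
    """Smooth band-limited target trajectory within the elbow range.

    A sum of 2-4 sinusoids with frequencies in ``freq_band`` is scaled to
    ``amplitude_deg`` around ``center_deg`` and tapered with raised-cosine
    ramps so the movement starts and ends at the home angle (0 deg).  With
    a zero harmonic count the trajectory is constant at the home angle.
    """
    if config.center_deg + config.amplitude_deg > 90.0 or (
        config.center_deg - config.amplitude_deg < 0.0
    ):
        raise ValueError("amplitude/center exceed the elbow joint range [0, 90] deg")
    n = config.n_samples
    t = np.arange(n) / config.rate_hz
    k_lo, k_hi = config.harmonics
    k = int(rng.integers(k_lo, k_hi + 1)) if k_hi > k_lo else k_lo
    if k == 0:
        return Trajectory(np.zeros(n), rate=config.rate_hz)
    freqs = rng.uniform(config.freq_band[0], config.freq_band[1], size=k)
    phases = rng.uniform(0.0, 2.0 * math.pi, size=k)
    weights = rng.uniform(0.5, 1.0, size=k)
    z = np.sum(
        weights[:, None] * np.sin(2.0 * math.pi * freqs[:, None] * t + phases[:, None]),
        axis=0,
    )
    z /= np.max(np.abs(z))
    core = config.center_deg + config.amplitude_deg * z
    # raised-cosine ramps to/from the home angle
    ramp_n = min(n // 2, int(round(config.taper_s * config.rate_hz)))
    window = np.ones(n)
    if ramp_n > 0:
        ramp = 0.5 * (1.0 - np.cos(math.pi * np.arange(ramp_n) / ramp_n))
        window[:ramp_n] = ramp
        window[-ramp_n:] = ramp[::-1]
    return Trajectory(core * window, rate=config.rate_hz)


def _smooth_noise(
    rng: np.random.Generator, n: int, rate: float, sd: float, kernel_s: float = 0.15
) -> np.ndarray:
    """Zero-mean low-pass noise with the requested sample SD."""
    if sd <= 0:
        return np.zeros(n)
    white = rng.normal(0.0, 1.0, size=n)
    kn = max(3, int(round(6 * kernel_s * rate)) | 1)
    x = np.arange(kn) - kn // 2
    kernel = np.exp(-0.5 * (x / (kernel_s * rate)) ** 2)
    kernel /= kernel.sum()
    smooth = np.convolve(white, kernel, mode="same")
    s = smooth.std()
    return smooth * (sd / s) if s > 0 else smooth


def generate_reproduction(
    profile: ParticipantProfile,
    target: Trajectory,
    phase: str,
    rng: np.random.Generator,
    distractor: Optional[Trajectory] = None,
    config: Optional[CohortConfig] = None,
    motor_noise_sd: float = DEFAULT_LINKS.motor_noise_sd,
) -> Trajectory:
    """Simulate one active reproduction of the target trajectory.

    The reproduction is a fidelity-weighted mixture ``rho * target +
    (1 - rho) * distractor`` plus smooth motor noise, with ``rho`` equal to
    the participant's pre- or post-learning fidelity.  The distractor
    stands for the participant's idiosyncratic default movement; callers
    simulating a session should draw it once per participant and pass it
    to every trial (as :func:`simulate_cohort` does).
    """
    if phase not in ("pre", "post"):
        raise ValueError(f"unknown phase {phase!r}; expected 'pre' or 'post'")
    rho = profile.rho_pre if phase == "pre" else profile.rho_post
    if distractor is None:
        cfg = config if config is not None else CohortConfig()
        cfg = replace(
            cfg,
            duration_s=len(target) / target.rate,
            rate_hz=target.rate,
        )
        distractor = _draw_distractor(cfg, target, rng)
    if len(distractor) != len(target) or distractor.rate != target.rate:
        raise ValueError("distractor must match the target's length and rate")
    noise = _smooth_noise(rng, len(target), target.rate, motor_noise_sd)
    samples = rho * target.samples + (1.0 - rho) * distractor.samples + noise
    return Trajectory(samples, rate=target.rate)


def _draw_distractor(
    config: CohortConfig,
    target: Trajectory,
    rng: np.random.Generator,
    max_tries: int = 50,
) -> Trajectory:
    """Draw a default movement genuinely unrelated to the target.

    Band-limited smooth signals can correlate substantially with each
    other at some lag by chance; a draw is rejected until its peak
    normalized cross-correlation with the target is below
    ``config.distractor_max_peak_r`` (the last draw is kept if the budget
    runs out).
    """
    from .trajectory_similarity import xcorr_peak

    distractor = generate_target_trajectory(config, rng)
    for _ in range(max_tries):
        peak, _ = xcorr_peak(target, distractor)
        if abs(peak) < config.distractor_max_peak_r:
            break
        distractor = generate_target_trajectory(config, rng)
    return distractor


@dataclass
class CohortData:
    """A fully simulated cohort: trial tables, trajectories, latent traits."""

    config: CohortConfig
    model: StructuralTraitModel
    profiles: list[ParticipantProfile]
    memory_trials: pd.DataFrame
    judgment_trials: pd.DataFrame
    target: Trajectory
    reproductions: dict[str, dict[str, list[Trajectory]]]  # pid -> phase -> trials

    @property
    def traits(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(p) for p in self.profiles])

    def participant_ids(self) -> list[str]:
        return [p.id for p in self.profiles]

    def save(self, out_dir: str | Path) -> None:
        """Write the CSV/YAML cohort layout (one directory per cohort)."""
        out = Path(out_dir)
        try:
            (out / "trajectories").mkdir(parents=True, exist_ok=True)
            self.memory_trials.to_csv(out / "memory_trials.csv", index=False)
            self.judgment_trials.to_csv(out / "judgment_trials.csv", index=False)
            self.traits.to_csv(out / "latent_traits.csv", index=False)
            cfg = {
                "config": asdict(self.config),
                "model": asdict(self.model),
            }
            with open(out / "cohort_config.yaml", "w") as fh:
                yaml.safe_dump(cfg, fh, sort_keys=True)
            self._write_traj(out / "trajectories" / "target.csv", self.target)
            for pid, phases in self.reproductions.items():
                for phase, reps in phases.items():
                    for i, rep in enumerate(reps, start=1):
                        self._write_traj(
                            out / "trajectories" / f"{pid}_{phase}_{i}.csv", rep
                        )
        except OSError as exc:
            raise OSError(f"failed writing cohort to {out}: {exc}") from exc

    @staticmethod
    def _write_traj(path: Path, traj: Trajectory) -> None:
        pd.DataFrame({"time_s": traj.times, "angle_deg": traj.samples}).to_csv(
            path, index=False, float_format="%.6f"
        )


def _memory_frame(pid: str, trials: list[MemoryTrial]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(t) for t in trials])
    df.insert(0, "participant_id", pid)
    df.insert(1, "trial", np.arange(1, len(trials) + 1))
    return df


def _judgment_frame(pid: str, trials: list[JudgmentTrial]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(t) for t in trials])
    df.insert(0, "participant_id", pid)
    df.insert(1, "trial", np.arange(1, len(trials) + 1))
    return df


def simulate_cohort(
    config: CohortConfig,
    model: StructuralTraitModel = StructuralTraitModel(),
    links: TraitLinkParams = DEFAULT_LINKS,
    out_dir: Optional[str | Path] = None,
) -> CohortData:
    """Simulate a full cohort: traits, sessions and trajectories.

    Deterministic given ``config.seed``; the same seed regenerates an
    identical dataset.  If ``out_dir`` is given the cohort is also written
    to disk in the standard CSV layout.
    """
    if config.n_participants < 1:
        raise ValueError("cohort must contain at least one participant")
    profiles = sample_traits(model, config.n_participants, config.seed, links)
    target = generate_target_trajectory(
        config, np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=_STREAM_TARGET))
    )
    memory_frames, judgment_frames = [], []
    reproductions: dict[str, dict[str, list[Trajectory]]] = {}
    for i, profile in enumerate(profiles):
        mem_rng = _participant_rng(config.seed, i, _STREAM_MEMORY)
        jud_rng = _participant_rng(config.seed, i, _STREAM_JUDGMENT)
        traj_rng = _participant_rng(config.seed, i, _STREAM_TRAJ)
        memory_frames.append(
            _memory_frame(
                profile.id,
                generate_memory_session(profile, config, mem_rng, links.sigma_floor),
            )
        )
        judgment_frames.append(
            _judgment_frame(
                profile.id, generate_judgment_session(profile, config, jud_rng)
            )
        )
        distractor = _draw_distractor(config, target, traj_rng)
        phases: dict[str, list[Trajectory]] = {"pre": [], "post": []}
        for phase, n_reps in (("pre", config.n_pre), ("post", config.n_post)):
            for _ in range(n_reps):
                phases[phase].append(
                    generate_reproduction(
                        profile,
                        target,
                        phase,
                        traj_rng,
                        distractor=distractor,
                        config=config,
                        motor_noise_sd=links.motor_noise_sd,
                    )
                )
        reproductions[profile.id] = phases

    cohort = CohortData(
        config=config,
        model=model,
        profiles=profiles,
        memory_trials=pd.concat(memory_frames, ignore_index=True),
        judgment_trials=pd.concat(judgment_frames, ignore_index=True),
        target=target,
        reproductions=reproductions,
    )
    if out_dir is not None:
        cohort.save(out_dir)
    return cohort
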