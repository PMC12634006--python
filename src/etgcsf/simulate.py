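"""Simulated child observers, synthetic gaze streams, cohorts, test-retest.

Nothing in this package requires hardware or human data: a
:class:`SimObserver` holds a ground-truth CSF plus behavioural nuisance
parameters (attention lapses, guessing, fixation jitter, fixation latency,
between-session variability), answers trials through the same Weibull
psychometric model the engine assumes (with the lapse folded in
generatively), and can emit a 65 Hz gaze stream that drives the AOI
adjudicator end to end.

Cohort sampling draws observers from plausible preschool parameter
distributions; :func:`run_test_retest` plays each subject through two
consecutive sessions — with small Gaussian jitter on the log-parameters
between runs, standing in for biological state changes — and returns the
paired scores that feed the reliability battery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .csf_model import CSFParams
from .engine import PsychometricConfig, QcsfEngine, Stimulus, p_correct
from .gaze import DEFAULT_GEOMETRY, DisplayGeometry, GazeStream, NOMINAL_SAMPLE_HZ
from .reliability import PairedScores
from .session import ProtocolConfig, SessionResult, run_session

__all__ = [
    "SimObserver",
    "CohortConfig",
    "DirectResponder",
    "GazeResponder",
    "respond",
    "synth_gaze",
    "sample_cohort",
    "run_test_retest",
    "TestRetestResult",
]


@dataclass(frozen=True)
class SimObserver:
    """Ground-truth observer: a true CSF plus behavioural nuisance parameters.

    lapse_rate
        Per-trial probability the child is not attending; on a lapse the
        response is a pure guess.
    guess
        Chance-correct probability during a lapse or non-detection (0.5 for
        the two-sided looking task).
    gaze_noise_deg
        Fixation jitter SD in degrees.
    latency_ms_lognormal
        (mu, sigma) of the natural-log-normal fixation latency in ms.
    session_jitter_sd
        SD of Gaussian perturbation applied to log10 CSF parameters between
        consecutive sessions (biological test-retest variability).
    invalid_rate
        Per-sample probability of a tracking dropout in synthetic gaze.
    """

    true_params: CSFParams
    lapse_rate: float = 0.05
    guess: float = 0.5
    gaze_noise_deg: float = 0.5
    latency_ms_lognormal: Tuple[float, float] = (math.log(500.0), 0.3)
    session_jitter_sd: float = 0.05
    invalid_rate: float = 0.02

    def __post_init__(self) -> None:
        if not (0 <= self.lapse_rate <= 1 and 0 <= self.guess <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.gaze_noise_deg < 0 or self.session_jitter_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        if not (0 <= self.invalid_rate < 1):
            raise ValueError("invalid_rate must lie in [0, 1)")


def respond(
    observer: SimObserver,
    stim: Stimulus,
    rng: np.random.Generator,
    psych: PsychometricConfig = PsychometricConfig(),
) -> str:
    """Generative response: lapse -> guess, otherwise lapse-free Weibull.

    Marginally, P(correct) = lapse * guess + (1 - lapse) * p_correct with
    the psychometric lapse set to zero — the generative twin of the
    engine's likelihood, with the observer's own lapse folded in.
    """
    if rng.random() < observer.lapse_rate:
        return "correct" if rng.random() < observer.guess else "incorrect"
    p = p_correct(observer.true_params, stim, replace(psych, lapse=0.0))
    return "correct" if rng.random() < p else "incorrect"


def _deg_to_px_arrays(geom: DisplayGeometry, x_deg, y_deg):
    scale = geom.px_per_cm * geom.viewing_distance_cm
    x = geom.width_px / 2.0 + scale * np.tan(np.radians(x_deg))
    y = geom.height_px / 2.0 - scale * np.tan(np.radians(y_deg))
    return x, y


def synth_gaze(
    observer: SimObserver,
    stim: Stimulus,
    intended: str,
    geom: DisplayGeometry = DEFAULT_GEOMETRY,
    rng: Optional[np.random.Generator] = None,
    eccentricity_deg: float = 7.0,
    duration_s: float = 4.0,
) -> GazeStream:
    """Synthesize a 65 Hz gaze stream realizing the intended outcome.

    intended = "correct": fixate the screen centre, then after a lognormal
    latency (clipped to 2 s so the dwell criterion can complete) fixate the
    target AOI centre with Gaussian jitter for the rest of the trial.

    intended = "incorrect": wander between waypoints drawn away from both
    candidate AOIs, switching every ~0.45 s, so consecutive in-AOI runs stay
    far below the 0.8 s dwell criterion.

    Tracking dropouts occur independently per sample at ``invalid_rate``.
    """
    if intended not in ("correct", "incorrect"):
        raise ValueError("intended must be 'correct' or 'incorrect'")
    rng = rng if rng is not None else np.random.default_rng()
    period_ms = 1000.0 / NOMINAL_SAMPLE_HZ
    t = np.arange(0.0, duration_s * 1000.0, period_ms)
    n = len(t)
    target_x = eccentricity_deg if stim.side == "right" else -eccentricity_deg

    if intended == "correct":
        mu, sigma = observer.latency_ms_lognormal
        latency = min(float(rng.lognormal(mu, sigma)), 2000.0)
        on_target = t >= latency
        x_deg = np.where(on_target, target_x, 0.0)
        y_deg = np.zeros(n)
    else:
        switch_every = max(1, int(round(450.0 / period_ms)))
        n_way = n // switch_every + 2
        wx = np.empty(n_way)
        wy = np.empty(n_way)
        for k in range(n_way):
            while True:
                cx = rng.uniform(-12.0, 12.0)
                cy = rng.uniform(-7.0, 7.0)
                # stay clear of both candidate AOIs (inflated by jitter)
                margin = 2.2 + 2.0 * observer.gaze_noise_deg + 0.3
                if (abs(abs(cx) - eccentricity_deg) > margin) or (abs(cy) > margin):
                    break
            wx[k], wy[k] = cx, cy
        seg = np.arange(n) / switch_every
        k0 = np.floor(seg).astype(int)
        frac = seg - k0
        x_deg = wx[k0] * (1 - frac) + wx[k0 + 1] * frac
        y_deg = wy[k0] * (1 - frac) + wy[k0 + 1] * frac

    if observer.gaze_noise_deg > 0:
        x_deg = x_deg + rng.normal(0.0, observer.gaze_noise_deg, n)
        y_deg = y_deg + rng.normal(0.0, observer.gaze_noise_deg, n)
    x_px, y_px = _deg_to_px_arrays(geom, x_deg, y_deg)
    valid = rng.random(n) >= observer.invalid_rate
    x_px = np.where(valid, x_px, 0.0)
    y_px = np.where(valid, y_px, 0.0)
    return GazeStream(t_ms=t, x_px=x_px, y_px=y_px, valid=valid)


class DirectResponder:
    """Responder returning outcome strings straight from the generative model."""

    def __init__(self, observer: SimObserver, psych: PsychometricConfig = PsychometricConfig()):
        self.observer = observer
        self.psych = psych

    def __call__(self, stim: Stimulus, rng: np.random.Generator) -> str:
        return respond(self.observer, stim, rng, self.psych)


class GazeResponder:
    """Responder that emits a synthetic gaze stream for the session to adjudicate."""

    def __init__(
        self,
        observer: SimObserver,
        psych: PsychometricConfig = PsychometricConfig(),
        geom: DisplayGeometry = DEFAULT_GEOMETRY,
        eccentricity_deg: float = 7.0,
    ):
        self.observer = observer
        self.psych = psych
        self.geom = geom
        self.eccentricity_deg = eccentricity_deg

    def __call__(self, stim: Stimulus, rng: np.random.Generator) -> GazeStream:
        intended = respond(self.observer, stim, rng, self.psych)
        return synth_gaze(
            self.observer, stim, intended, self.geom, rng,
            eccentricity_deg=self.eccentricity_deg,
        )


@dataclass(frozen=True)
class CohortConfig:
    """Sampling distributions for a simulated preschool cohort.

    Defaults: log10 peak sensitivity ~ Normal(1.4, 0.2) truncated to the
    engine grid range; peak frequency log-normal with median 2.5 cpd and
    sigma 0.15 log10 units; bandwidth ~ Normal(3.5, 0.8) octaves truncated
    to [1, 9]; truncation depth ~ Uniform(0.2, 1.0); lapse ~ Uniform(0, 0.15).
    """

    n_subjects: int = 28
    seed: int = 0
    log10_gamma_mean: float = 1.4
    log10_gamma_sd: float = 0.2
    log10_gamma_bounds: Tuple[float, float] = (math.log10(1.05), 3.0)
    f_max_median: float = 2.5
    f_max_sigma_log10: float = 0.15
    f_max_bounds: Tuple[float, float] = (0.2, 20.0)
    beta_mean: float = 3.5
    beta_sd: float = 0.8
    beta_bounds: Tuple[float, float] = (1.0, 9.0)
    delta_bounds: Tuple[float, float] = (0.2, 1.0)
    lapse_bounds: Tuple[float, float] = (0.0, 0.15)
    observer_defaults: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("log10_gamma_sd", "f_max_sigma_log10", "beta_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("log10_gamma_bounds", "f_max_bounds", "beta_bounds",
                     "delta_bounds", "lapse_bounds"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be an ordered pair")


def _trunc_normal(rng, mean, sd, lo, hi):
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    while True:
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)


def sample_cohort(config: CohortConfig) -> List[SimObserver]:
    """Seeded, reproducible cohort draw; every draw satisfies CSF invariants."""
    rng = np.random.default_rng(config.seed)
    cohort = []
    for _ in range(config.n_subjects):
        lg = _trunc_normal(rng, config.log10_gamma_mean, config.log10_gamma_sd,
                           *config.log10_gamma_bounds)
        lf = _trunc_normal(
            rng,
            math.log10(config.f_max_median),
            config.f_max_sigma_log10,
            math.log10(config.f_max_bounds[0]),
            math.log10(config.f_max_bounds[1]),
        )
        beta = _trunc_normal(rng, config.beta_mean, config.beta_sd, *config.beta_bounds)
        delta = float(rng.uniform(*config.delta_bounds))
        lapse = float(rng.uniform(*config.lapse_bounds))
        params = CSFParams(gamma_max=10.0**lg, f_max=10.0**lf, beta=beta, delta=delta)
        cohort.append(
            SimObserver(true_params=params, lapse_rate=lapse, **config.observer_defaults)
        )
    return cohort


def _jitter_params(params: CSFParams, sd: float, rng: np.random.Generator) -> CSFParams:
    if sd == 0:
        return params
    lg = math.log10(params.gamma_max) + rng.normal(0, sd)
    lf = math.log10(params.f_max) + rng.normal(0, sd)
    lb = math.log10(params.beta) + rng.normal(0, sd)
    ld = math.log10(params.delta) + rng.normal(0, sd) if params.delta > 0 else None
    return CSFParams(
        gamma_max=max(10.0**lg, 1.0 + 1e-9),
        f_max=10.0**lf,
        beta=10.0**lb,
        delta=10.0**ld if ld is not None else 0.0,
    )


@dataclass
class TestRetestResult:
    """Paired per-subject scores for each outcome metric, plus durations."""

    scores: Dict[str, PairedScores]
    durations_trials: np.ndarray  # (n_subjects, 2) presented-trial counts
    sessions: List[Tuple[SessionResult, SessionResult]]


def run_test_retest(
    cohort: List[SimObserver],
    protocol: ProtocolConfig,
    seed: int,
    use_gaze: bool = False,
    psych: PsychometricConfig = PsychometricConfig(),
    engine: Optional[QcsfEngine] = None,
) -> TestRetestResult:
    """Two consecutive sessions per subject; returns paired outcome metrics.

    Between the two runs each subject's true log-parameters receive
    independent Gaussian jitter of SD ``session_jitter_sd``, emulating
    within-day biological variability.  Sessions are otherwise independent
    (fresh RNG streams derived from ``seed``).
    """
    eng = engine if engine is not None else QcsfEngine(protocol.engine_config())
    master = np.random.default_rng(seed)
    n = len(cohort)
    aul = np.empty((n, 2))
    acu = np.empty((n, 2))
    durations = np.empty((n, 2), dtype=int)
    sessions = []
    for i, obs in enumerate(cohort):
        pair = []
        for s in range(2):
            jit_rng = np.random.default_rng(master.integers(2**31))
            sess_seed = int(master.integers(2**31))
            obs_s = replace(
                obs,
                true_params=_jitter_params(obs.true_params, obs.session_jitter_sd, jit_rng),
            )
            responder = (
                GazeResponder(obs_s, psych, eccentricity_deg=protocol.eccentricity_deg)
                if use_gaze
                else DirectResponder(obs_s, psych)
            )
            result = run_session(protocol, responder, sess_seed, engine=eng)
            if not result.complete or result.estimate is None:
                raise RuntimeError(f"session failed for subject {i}, run {s}")
            aul[i, s] = result.estimate.aulcsf
            acu[i, s] = result.estimate.csf_acuity_logmar
            durations[i, s] = result.n_presented
            pair.append(result)
        sessions.append(tuple(pair))
    ids = [f"S{i:03d}" for i in range(n)]
    return TestRetestResult(
        scores={
            "aulcsf": PairedScores(
                subject_ids=ids, test=aul[:, 0], retest=aul[:, 1],
                label="aulcsf", units="log10 units",
            ),
            "csf_acuity_logmar": PairedScores(
                subject_ids=ids, test=acu[:, 0], retest=acu[:, 1],
                label="csf_acuity_logmar", units="logMAR",
            ),
        },
        durations_trials=durations,
        sessions=sessions,
    )
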