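"""Session orchestration: protocol presets, trial loop, cues, Gabor raster.

A session runs the adaptive loop until the protocol's number of *valid*
trials is reached: select the next stimulus by expected information gain,
randomize side and orientation, obtain a response (a direct outcome or a
gaze stream that is adjudicated against the stimulus AOI), update the
posterior on valid outcomes, and keep the child engaged through cue events —
an attention cue before every presentation, reward/motivation feedback after
each outcome, a bonus cue on every third consecutive correct response and a
task re-instruction cue on every third consecutive incorrect one.

Two protocol presets mirror the instrument's two deployments: the baseline
protocol (60 trials, 0.5-32 cpd) and the optimized pediatric protocol
(30 trials, 0.5-15 cpd).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .csf_model import DEFAULT_BAND, FrequencyBand
from .engine import (
    CSFEstimate,
    EngineConfig,
    QcsfEngine,
    Stimulus,
)
from .gaze import (
    DEFAULT_GEOMETRY,
    AdjudicationRule,
    DisplayGeometry,
    GazeStream,
    TrialOutcome,
    adjudicate_trial,
    aoi_for_stimulus,
)

__all__ = [
    "ProtocolConfig",
    "TrialRecord",
    "CueEvent",
    "SessionResult",
    "AliasingError",
    "protocol_preset",
    "run_session",
    "cue_for",
    "render_gabor",
]

#: Responders map a stimulus (plus the session RNG) to either a direct
#: outcome string, a TrialOutcome, or a raw GazeStream to be adjudicated.
Responder = Callable[[Stimulus, np.random.Generator], Union[str, TrialOutcome, GazeStream]]


class AliasingError(ValueError):
    """Requested grating frequency is below 2 px/cycle at this geometry."""


@dataclass(frozen=True)
class ProtocolConfig:
    """A complete test protocol: trial budget, stimulus range, geometry, rules."""

    name: str
    n_trials: int
    sf_range: Tuple[float, float]
    eccentricity_deg: float = 7.0
    stim_radius_deg: float = 2.0
    ramp_deg: float = 0.5
    rule: AdjudicationRule = field(default_factory=AdjudicationRule)
    engine: Optional[EngineConfig] = None
    band: FrequencyBand = DEFAULT_BAND

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not (0 < self.sf_range[0] < self.sf_range[1]):
            raise ValueError("sf_range must be an increasing positive pair")

    def engine_config(self) -> EngineConfig:
        cfg = self.engine if self.engine is not None else EngineConfig()
        return replace(cfg, sf_range=tuple(self.sf_range))


def protocol_preset(name: str, **overrides) -> ProtocolConfig:
    """Named protocol presets.

    ``exp1``: 60 valid trials, stimulus frequencies 0.5-32 cpd (baseline).
    ``exp2``: 30 valid trials, frequencies 0.5-15 cpd (optimized pediatric).
    """
    presets = {
        "exp1": dict(name="exp1", n_trials=60, sf_range=(0.5, 32.0)),
        "exp2": dict(name="exp2", n_trials=30, sf_range=(0.5, 15.0)),
    }
    if name not in presets:
        raise ValueError(f"unknown protocol preset {name!r}; use 'exp1' or 'exp2'")
    kwargs = {**presets[name], **overrides}
    return ProtocolConfig(**kwargs)


@dataclass(frozen=True)
class CueEvent:
    """An engagement cue emitted during the session."""

    kind: str  # attention | reward | motivation | bonus | instruction
    trial_idx: int


@dataclass
class TrialRecord:
    """One presentation: stimulus, adjudicated outcome, posterior entropy."""

    trial_idx: int
    stimulus: Stimulus
    outcome: str
    latency_ms: Optional[float]
    posterior_entropy: float
    cues: List[str]
    valid_idx: Optional[int] = None


@dataclass
class SessionResult:
    """Full trial log plus the final posterior-based CSF estimate."""

    protocol: str
    seed: int
    records: List[TrialRecord]
    cue_events: List[CueEvent]
    estimate: Optional[CSFEstimate]
    n_valid: int
    n_invalid: int
    complete: bool

    @property
    def n_presented(self) -> int:
        return len(self.records)


def cue_for(outcome_history: Sequence[str]) -> List[str]:
    """Post-outcome cues for the latest trial given the outcome history.

    Every valid outcome earns ``reward`` (correct) or ``motivation``
    (incorrect).  When the trailing run of consecutive correct responses —
    counted over valid outcomes only; invalid trials neither extend nor
    reset a streak — reaches 3, 6, 9, ... a ``bonus`` cue is added; a run of
    incorrect responses likewise triggers ``instruction``.  The pre-stimulus
    ``attention`` cue is emitted per presentation by :func:`run_session`,
    not here.
    """
    if not outcome_history:
        return []
    last = outcome_history[-1]
    if last == "invalid":
        return []
    cues = ["reward" if last == "correct" else "motivation"]
    valid = [o for o in outcome_history if o != "invalid"]
    run = 0
    for o in reversed(valid):
        if o == last:
            run += 1
        else:
            break
    if run >= 3 and run % 3 == 0:
        cues.append("bonus" if last == "correct" else "instruction")
    return cues


def _resolve_outcome(
    raw: Union[str, TrialOutcome, GazeStream],
    stim: Stimulus,
    protocol: ProtocolConfig,
    geom: DisplayGeometry,
) -> TrialOutcome:
    if isinstance(raw, TrialOutcome):
        return raw
    if isinstance(raw, GazeStream):
        aoi = aoi_for_stimulus(stim.side, protocol.eccentricity_deg)
        return adjudicate_trial(raw, aoi, protocol.rule, geom)
    if raw in ("correct", "incorrect", "invalid"):
        return TrialOutcome(result=raw)
    raise TypeError(f"responder returned unsupported value {raw!r}")


def run_session(
    protocol: ProtocolConfig,
    responder: Responder,
    seed: int,
    engine: Optional[QcsfEngine] = None,
    geom: DisplayGeometry = DEFAULT_GEOMETRY,
    max_presentations: Optional[int] = None,
) -> SessionResult:
    """Run one adaptive session to ``protocol.n_trials`` valid trials.

    Invalid (tracking-loss) trials are re-presented with a freshly selected
    stimulus and leave the posterior untouched, so normal completion always
    yields exactly the protocol's valid-trial count.  The run is
    bit-reproducible given the seed and a deterministic responder.  If the
    responder raises, the partial log is returned with ``complete=False``
    and no final estimate.
    """
    from .engine import posterior_entropy  # local to avoid cluttering namespace

    rng = np.random.default_rng(seed)
    eng = engine if engine is not None else QcsfEngine(protocol.engine_config())
    post = eng.new_posterior()
    records: List[TrialRecord] = []
    cue_events: List[CueEvent] = []
    history: List[str] = []
    n_valid = 0
    n_invalid = 0
    limit = max_presentations if max_presentations is not None else 20 * protocol.n_trials
    complete = True

    while n_valid < protocol.n_trials and len(records) < limit:
        idx = len(records)
        cue_events.append(CueEvent("attention", idx))
        stim = eng.select_stimulus(post, rng)
        try:
            raw = responder(stim, rng)
            outcome = _resolve_outcome(raw, stim, protocol, geom)
        except Exception:
            complete = False
            break
        history.append(outcome.result)
        cues = cue_for(history)
        for kind in cues:
            cue_events.append(CueEvent(kind, idx))
        valid_idx = None
        if outcome.result in ("correct", "incorrect"):
            post = eng.update(post, stim, outcome.result)
            valid_idx = n_valid
            n_valid += 1
        else:
            n_invalid += 1
        records.append(
            TrialRecord(
                trial_idx=idx,
                stimulus=stim,
                outcome=outcome.result,
                latency_ms=outcome.latency_ms,
                posterior_entropy=posterior_entropy(post),
                cues=cues,
                valid_idx=valid_idx,
            )
        )

    if n_valid < protocol.n_trials:
        complete = False
    estimate = eng.estimate_metrics(post, protocol.band) if complete else None
    return SessionResult(
        protocol=protocol.name,
        seed=seed,
        records=records,
        cue_events=cue_events,
        estimate=estimate,
        n_valid=n_valid,
        n_invalid=n_invalid,
        complete=complete,
    )


def render_gabor(
    stim: Stimulus,
    geom: DisplayGeometry = DEFAULT_GEOMETRY,
    mean_luminance: float = 0.5,
    radius_deg: float = 2.0,
    ramp_deg: float = 0.5,
) -> np.ndarray:
    """Normalized-luminance raster of the grating patch.

    A sinusoidal grating (sine phase, so the patch mean equals the background)
    at ``stim.sf`` cycles/degree and ``stim.orientation``, with amplitude
    ``contrast * mean_luminance``, windowed by a disc of ``radius_deg``: the
    envelope is 1 inside ``radius_deg - ramp_deg`` and falls along a
    half-Gaussian over the outer ``ramp_deg`` annulus (sigma = ramp/2.5, so
    the edge sits at 2.5 sigma, ~1.5% residual amplitude).

    Raises :class:`AliasingError` when the grating would fall below
    2 px/cycle at this geometry.
    """
    if not (0 <= mean_luminance <= 1):
        raise ValueError("mean_luminance must be in [0, 1]")
    px_per_deg = geom.px_per_deg
    if px_per_deg / stim.sf < 2.0:
        raise AliasingError(
            f"sf={stim.sf} cpd needs {px_per_deg / stim.sf:.2f} px/cycle "
            f"(< 2) at this geometry"
        )
    half_px = int(math.ceil(radius_deg * px_per_deg))
    ax = np.arange(-half_px, half_px + 1) / px_per_deg  # degrees, odd-sized
    x, y = np.meshgrid(ax, ax)
    theta = math.radians(stim.orientation)
    phase = 2.0 * math.pi * stim.sf * (x * math.cos(theta) + y * math.sin(theta))
    grating = np.sin(phase)
    r = np.hypot(x, y)
    sigma = ramp_deg / 2.5
    inner = radius_deg - ramp_deg
    envelope = np.where(
        r <= inner,
        1.0,
        np.where(r <= radius_deg, np.exp(-((r - inner) ** 2) / (2.0 * sigma**2)), 0.0),
    )
    raster = mean_luminance * (1.0 + stim.contrast * envelope * grating)
    return np.clip(raster, 0.0, 1.0)
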