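"""Gaze-based trial adjudication: AOI dwell rules and display geometry.

In a gaze-contingent preferential-looking trial the child "answers" by
looking at the grating.  A trial is scored **correct** when gaze stays inside
a rectangular area of interest (AOI) centred on the stimulus — 4.4 degrees of
visual angle on a side — for a sustained dwell of at least 0.8 s; failing
that within a 4 s deadline from stimulus onset scores **incorrect**.  Streams
dominated by tracking loss are scored **invalid** so the session controller
can re-present the trial without updating the posterior.

Screen coordinates follow the remote-tracker convention: pixels, origin at
the top-left, y down.  All science-side geometry is in degrees of visual
angle from the screen centre, x right and y up; the conversion is a per-axis
flat-screen tangent mapping assuming square pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "DisplayGeometry",
    "GazeStream",
    "AOI",
    "AdjudicationRule",
    "TrialOutcome",
    "DEFAULT_GEOMETRY",
    "NOMINAL_SAMPLE_HZ",
    "deg_to_px",
    "px_to_deg",
    "aoi_for_stimulus",
    "adjudicate_trial",
]

#: Nominal sampling rate of the remote eye tracker (Hz).
NOMINAL_SAMPLE_HZ = 65.0


@dataclass(frozen=True)
class DisplayGeometry:
    """Physical display model: resolution, diagonal size, viewing distance."""

    width_px: int = 2560
    height_px: int = 1440
    diagonal_inches: float = 27.0
    viewing_distance_cm: float = 60.0

    def __post_init__(self) -> None:
        if min(self.width_px, self.height_px) <= 0:
            raise ValueError("resolution must be positive")
        if self.diagonal_inches <= 0 or self.viewing_distance_cm <= 0:
            raise ValueError("physical dimensions must be positive")

    @property
    def width_cm(self) -> float:
        diag_px = math.hypot(self.width_px, self.height_px)
        return self.diagonal_inches * 2.54 * self.width_px / diag_px

    @property
    def px_per_cm(self) -> float:
        return self.width_px / self.width_cm

    @property
    def px_per_deg(self) -> float:
        """Small-angle pixel density at screen centre (px per degree)."""
        return (
            self.px_per_cm
            * self.viewing_distance_cm
            * math.tan(math.radians(1.0))
        )


#: 27-inch 2560x1440 monitor viewed at 60 cm — the instrument's setup.
DEFAULT_GEOMETRY = DisplayGeometry()


@dataclass
class GazeStream:
    """Timestamped gaze samples for one trial.

    ``t_ms`` is time since stimulus onset; ``x_px``/``y_px`` are screen
    pixels (top-left origin, y down); ``valid`` flags tracked samples.
    """

    t_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t_ms)
        if not (len(self.x_px) == len(self.y_px) == len(self.valid) == n):
            raise ValueError("gaze stream columns must have equal length")
        if n > 1 and np.any(np.diff(self.t_ms) < 0):
            raise ValueError("timestamps must be nondecreasing")

    def __len__(self) -> int:
        return len(self.t_ms)


@dataclass(frozen=True)
class AOI:
    """Axis-aligned rectangular area of interest, in degrees from centre."""

    center_deg: Tuple[float, float]
    half_extent_deg: Tuple[float, float] = (2.2, 2.2)

    def __post_init__(self) -> None:
        if min(self.half_extent_deg) <= 0:
            raise ValueError("half_extent_deg must be positive")

    def contains(self, x_deg, y_deg):
        cx, cy = self.center_deg
        hx, hy = self.half_extent_deg
        return (np.abs(np.asarray(x_deg) - cx) <= hx) & (
            np.abs(np.asarray(y_deg) - cy) <= hy
        )


@dataclass(frozen=True)
class AdjudicationRule:
    """Dwell/timeout rule converting a gaze stream into a trial outcome.

    dwell_s
        Sustained in-AOI dwell required for a correct response (0.8 s).
    timeout_s
        Trial deadline from stimulus onset; failing the dwell criterion by
        then scores incorrect (4 s).
    gap_tolerance_ms
        Maximum invalid/missing gap bridged inside a dwell run; covers
        blinks and brief tracker dropouts.
    max_invalid_fraction
        If the fraction of invalid samples exceeds this, the whole trial is
        invalid (tracking loss).
    """

    dwell_s: float = 0.8
    timeout_s: float = 4.0
    gap_tolerance_ms: float = 100.0
    max_invalid_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.dwell_s < self.timeout_s):
            raise ValueError("require 0 < dwell_s < timeout_s")


@dataclass(frozen=True)
class TrialOutcome:
    """Adjudicated trial result.

    ``result`` is one of ``correct``, ``incorrect``, ``invalid``;
    ``latency_ms`` is the time the dwell criterion was met (correct only);
    ``dwell_fraction`` is the fraction of valid samples inside the AOI;
    ``invalid_reason`` distinguishes an empty stream from tracking loss.
    """

    result: str
    latency_ms: Optional[float] = None
    dwell_fraction: float = 0.0
    invalid_reason: Optional[str] = None


def deg_to_px(
    geom: DisplayGeometry, point_deg: Tuple[float, float]
) -> Tuple[float, float]:
    """Degrees-from-centre (x right, y up) -> screen pixels (top-left, y down).

    Per-axis tangent mapping: the physical offset on the screen is
    ``viewing_distance * tan(angle)``, converted to pixels via the display's
    pixel density, then shifted so (0, 0) deg lands on the screen centre.
    """
    ax, ay = point_deg
    if abs(ax) >= 90 or abs(ay) >= 90:
        raise ValueError("angles must be < 90 degrees in magnitude")
    scale = geom.px_per_cm * geom.viewing_distance_cm
    x = geom.width_px / 2.0 + scale * math.tan(math.radians(ax))
    y = geom.height_px / 2.0 - scale * math.tan(math.radians(ay))
    return (x, y)


def px_to_deg(
    geom: DisplayGeometry, point_px: Tuple[float, float]
) -> Tuple[float, float]:
    """Inverse of :func:`deg_to_px`; round-trips to numerical precision."""
    x, y = point_px
    scale = geom.px_per_cm * geom.viewing_distance_cm
    ax = math.degrees(math.atan((x - geom.width_px / 2.0) / scale))
    ay = math.degrees(math.atan((geom.height_px / 2.0 - y) / scale))
    return (ax, ay)


def _px_to_deg_arrays(geom, x_px, y_px):
    scale = geom.px_per_cm * geom.viewing_distance_cm
    ax = np.degrees(np.arctan((np.asarray(x_px) - geom.width_px / 2.0) / scale))
    ay = np.degrees(np.arctan((geom.height_px / 2.0 - np.asarray(y_px)) / scale))
    return ax, ay


def aoi_for_stimulus(
    side: str,
    eccentricity_deg: float = 7.0,
    half_extent_deg: Tuple[float, float] = (2.2, 2.2),
) -> AOI:
    """AOI centred on the stimulus location for the given side.

    Targets sit on the horizontal midline at ±``eccentricity_deg`` (7° in the
    deployed protocol); the AOI is a square of side 4.4° of visual angle.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    sign = 1.0 if side == "right" else -1.0
    return AOI(center_deg=(sign * eccentricity_deg, 0.0), half_extent_deg=half_extent_deg)


def _nominal_period_ms(t_ms: np.ndarray) -> float:
    if len(t_ms) > 1:
        dt = np.diff(t_ms)
        dt = dt[dt > 0]
        if len(dt):
            return float(np.median(dt))
    return 1000.0 / NOMINAL_SAMPLE_HZ


def adjudicate_trial(
    stream: GazeStream,
    aoi: AOI,
    rule: AdjudicationRule = AdjudicationRule(),
    geom: DisplayGeometry = DEFAULT_GEOMETRY,
) -> TrialOutcome:
    """Score one trial from its gaze stream.

    A *dwell run* is a sequence of valid in-AOI samples in which successive
    members are at most ``gap_tolerance_ms`` apart (invalid samples or short
    dropouts inside a run are bridged; a valid sample outside the AOI always
    breaks the run).  Each sample is taken to cover one nominal sample period
    (the stream's median inter-sample interval), so a run of samples at
    ``t_first .. t_last`` spans ``t_last - t_first + period``.  At 65 Hz the
    0.8 s dwell criterion is met by exactly 52 consecutive samples.

    Outcome: **correct** at the moment the first run's span reaches
    ``dwell_s``, **incorrect** at the deadline otherwise, **invalid** when the
    stream is empty or its invalid-sample fraction exceeds
    ``max_invalid_fraction``.  Samples after the deadline are ignored.
    """
    timeout_ms = rule.timeout_s * 1000.0
    dwell_ms = rule.dwell_s * 1000.0
    eps = 1e-9

    keep = stream.t_ms <= timeout_ms + eps
    t = stream.t_ms[keep]
    if len(t) == 0:
        return TrialOutcome(result="invalid", invalid_reason="empty_stream")
    valid = stream.valid[keep]
    n_invalid = int(np.count_nonzero(~valid))
    invalid_fraction = n_invalid / len(t)

    x_deg, y_deg = _px_to_deg_arrays(geom, stream.x_px[keep], stream.y_px[keep])
    in_aoi = aoi.contains(x_deg, y_deg) & valid
    n_valid = len(t) - n_invalid
    dwell_fraction = (
        float(np.count_nonzero(in_aoi)) / n_valid if n_valid else 0.0
    )

    if invalid_fraction > rule.max_invalid_fraction:
        return TrialOutcome(
            result="invalid",
            dwell_fraction=dwell_fraction,
            invalid_reason="tracking_loss",
        )

    period = _nominal_period_ms(t)
    run_start = None
    last_in = None
    for i in range(len(t)):
        if in_aoi[i]:
            ti = t[i]
            if run_start is None or ti - last_in > rule.gap_tolerance_ms + eps:
                run_start = ti
            last_in = ti
            if ti - run_start + period >= dwell_ms - eps:
                latency = ti + period
                if latency <= timeout_ms + eps:
                    return TrialOutcome(
                        result="correct",
                        latency_ms=float(latency),
                        dwell_fraction=dwell_fraction,
                    )
        elif valid[i]:
            # a tracked sample outside the AOI always breaks the run;
            # untracked samples are bridged via the gap tolerance
            run_start = None
            last_in = None
    return TrialOutcome(result="incorrect", dwell_fraction=dwell_fraction)
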