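"""Truncated log-parabola contrast sensitivity function and derived metrics.

The contrast sensitivity function (CSF) gives sensitivity — the reciprocal of
the contrast detection threshold — as a function of spatial frequency.  The
model used throughout this package is the four-parameter truncated
log-parabola standard in adaptive CSF estimation:

* ``gamma_max`` — peak sensitivity (linear units, > 1),
* ``f_max`` — spatial frequency of the peak (cycles per degree),
* ``beta`` — full bandwidth at half-maximum sensitivity (octaves),
* ``delta`` — truncation depth on the low-frequency side (log10 units).

In log10 coordinates the curve is a downward parabola in log spatial
frequency, floored at ``log10(gamma_max) - delta`` for frequencies below the
peak.  Two scalar summaries are derived from a fitted curve:

* **AULCSF** — the area under the log CSF over a fixed frequency band
  (default 1.5–18 cpd), integrating with respect to log10 frequency;
* **CSF acuity** — the frequency at which sensitivity falls to 1
  (100 % contrast threshold), reported both in cpd and as a logMAR
  equivalent anchored at 30 cpd = logMAR 0.

The fitted curve may extend beyond the stimulus frequencies actually
presented; nothing here clamps to a protocol range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CSFParams",
    "CutoffResult",
    "FrequencyBand",
    "DEFAULT_BAND",
    "log_sensitivity",
    "csf_acuity",
    "aulcsf",
]

_LOG10_2 = math.log10(2.0)


@dataclass(frozen=True)
class CSFParams:
    """Parameters of the truncated log-parabola CSF.

    Attributes
    ----------
    gamma_max : float
        Peak linear contrast sensitivity; must exceed 1.
    f_max : float
        Peak spatial frequency in cycles per degree; positive.
    beta : float
        Full bandwidth at half-maximum sensitivity, in octaves; positive.
    delta : float
        Low-frequency truncation depth in log10 sensitivity units; >= 0.
    """

    gamma_max: float
    f_max: float
    beta: float
    delta: float

    def __post_init__(self) -> None:
        for name in ("gamma_max", "f_max", "beta", "delta"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.gamma_max <= 1:
            raise ValueError(f"gamma_max must be > 1, got {self.gamma_max}")
        if self.f_max <= 0:
            raise ValueError(f"f_max must be > 0, got {self.f_max}")
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")


@dataclass(frozen=True)
class CutoffResult:
    """High-frequency cutoff of the CSF: cpd value and logMAR equivalent."""

    f_cutoff: float
    logmar: float


@dataclass(frozen=True)
class FrequencyBand:
    """A spatial-frequency band [f_lo, f_hi] in cycles per degree."""

    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(
                f"band requires 0 < f_lo < f_hi, got ({self.f_lo}, {self.f_hi})"
            )


#: Band over which AULCSF is reported: 1.5 to 18 cpd.
DEFAULT_BAND = FrequencyBand(1.5, 18.0)


def log_sensitivity(params, f):
    """Log10 contrast sensitivity of the truncated log-parabola at frequency f.

    With ``beta_prime = beta * log10(2)`` (bandwidth converted from octaves to
    log10-frequency units), the parabola is::

        log10(gamma_max) - 4 log10(2) * ((log10 f - log10 f_max) / beta_prime)^2

    Above the peak the parabola applies unmodified; below the peak the value
    is floored at ``log10(gamma_max) - delta``.

    Parameters
    ----------
    params : CSFParams
    f : float or array_like
        Spatial frequency in cpd, strictly positive.  Vectorized.

    Returns
    -------
    float or ndarray of log10 sensitivity.
    """
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr <= 0):
        raise ValueError("spatial frequency must be > 0")
    log_gamma = math.log10(params.gamma_max)
    beta_prime = params.beta * _LOG10_2
    u = (np.log10(f_arr) - math.log10(params.f_max)) / beta_prime
    parabola = log_gamma - 4.0 * _LOG10_2 * u * u
    floor = log_gamma - params.delta
    out = np.where(f_arr < params.f_max, np.maximum(parabola, floor), parabola)
    if np.isscalar(f) or np.ndim(f) == 0:
        return float(out)
    return out


def csf_acuity(params: CSFParams) -> CutoffResult:
    """Frequency where log sensitivity hits 0 on the high-frequency branch.

    Solves the parabola analytically::

        log10 f_cutoff = log10 f_max + (beta_prime / 2) * sqrt(log10 gamma_max / log10 2)

    and converts to a logMAR equivalent via ``logmar = log10(30 / f_cutoff)``,
    anchoring 30 cpd to logMAR 0 (the standard cpd <-> Snellen-decimal
    correspondence).

    Raises
    ------
    ValueError
        If ``gamma_max <= 1``; the curve then never exceeds sensitivity 1 and
        no crossing exists.  (CSFParams already enforces gamma_max > 1.)
    """
    if params.gamma_max <= 1:
        raise ValueError("no zero crossing: gamma_max must exceed 1")
    beta_prime = params.beta * _LOG10_2
    log_fc = math.log10(params.f_max) + 0.5 * beta_prime * math.sqrt(
        math.log10(params.gamma_max) / _LOG10_2
    )
    f_cutoff = 10.0**log_fc
    return CutoffResult(f_cutoff=f_cutoff, logmar=math.log10(30.0 / f_cutoff))


def aulcsf(
    params: CSFParams,
    band: FrequencyBand = DEFAULT_BAND,
    n_grid: int = 1024,
) -> float:
    """Area under the log CSF over ``band``, w.r.t. log10 spatial frequency.

    The integrand is ``max(log_sensitivity(f), 0)``: frequencies where
    sensitivity drops below 1 contribute nothing.  Trapezoidal rule on an
    evenly spaced log10-frequency grid; deterministic for a fixed grid.

    Parameters
    ----------
    params : CSFParams
    band : FrequencyBand
        Integration limits in cpd; default 1.5–18.
    n_grid : int
        Number of grid points, >= 512.
    """
    if n_grid < 512:
        raise ValueError("n_grid must be >= 512 for the documented accuracy")
    log_f = np.linspace(math.log10(band.f_lo), math.log10(band.f_hi), n_grid)
    integrand = np.clip(log_sensitivity(params, 10.0**log_f), 0.0, None)
    return float(np.trapezoid(integrand, log_f))
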