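"""File formats: gaze CSV, trial-log JSONL, score tables, configs, manifests.

Conventions on disk: angles in degrees, times in milliseconds; log-unit
quantities carry a ``_log10``/``logmar`` suffix in column names so units
never drift silently.  Gaze CSVs use the remote-tracker pixel convention
(columns ``t_ms, x_px, y_px, valid`` with an optional ``trial_idx`` for
one-file-per-session dialects).  Trial logs are JSONL (one record per line,
streamable and append-safe); score tables are CSV; configuration is YAML or
JSON with an identical schema.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .engine import Posterior, Stimulus
from .gaze import GazeStream
from .reliability import PairedScores
from .session import SessionResult

__all__ = [
    "GazeFile",
    "RunManifest",
    "read_gaze_csv",
    "write_gaze_csv",
    "write_trial_log",
    "read_trial_log",
    "write_session_summary",
    "write_paired_scores",
    "read_paired_scores",
    "export_posterior",
    "load_config",
    "write_manifest",
]

_GAZE_COLUMNS = ("t_ms", "x_px", "y_px", "valid")


@dataclass
class GazeFile:
    """Parsed gaze CSV: one stream per trial index (None when absent)."""

    streams: Dict[Optional[int], GazeStream]
    n_malformed: int
    n_inversions: int

    @property
    def stream(self) -> GazeStream:
        if len(self.streams) != 1:
            raise ValueError("file contains multiple trials; use .streams")
        return next(iter(self.streams.values()))


def read_gaze_csv(path: Union[str, Path]) -> GazeFile:
    """Read a gaze CSV; sort per-stream by time; count bad rows/inversions.

    Requires a header with columns ``t_ms, x_px, y_px, valid``; an optional
    ``trial_idx`` column splits the file into one stream per trial.  Rows
    with non-numeric values are dropped and counted; non-monotone
    timestamps are stably sorted and each adjacent inversion counted.
    """
    df = pd.read_csv(path)
    for col in _GAZE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"gaze CSV {path} is missing required column {col!r}")
    has_trials = "trial_idx" in df.columns
    cols = list(_GAZE_COLUMNS) + (["trial_idx"] if has_trials else [])
    numeric = df[cols].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    n_malformed = int(bad.sum())
    numeric = numeric[~bad]

    streams: Dict[Optional[int], GazeStream] = {}
    n_inversions = 0
    groups = (
        [(int(k), g) for k, g in numeric.groupby("trial_idx", sort=True)]
        if has_trials
        else [(None, numeric)]
    )
    for key, g in groups:
        t = g["t_ms"].to_numpy(dtype=float)
        n_inversions += int(np.sum(np.diff(t) < 0))
        order = np.argsort(t, kind="stable")
        streams[key] = GazeStream(
            t_ms=t[order],
            x_px=g["x_px"].to_numpy(dtype=float)[order],
            y_px=g["y_px"].to_numpy(dtype=float)[order],
            valid=g["valid"].to_numpy()[order].astype(float) > 0,
        )
    return GazeFile(streams=streams, n_malformed=n_malformed, n_inversions=n_inversions)


def write_gaze_csv(
    stream: GazeStream, path: Union[str, Path], trial_idx: Optional[int] = None
) -> None:
    df = pd.DataFrame(
        {
            "t_ms": np.round(stream.t_ms, 4),
            "x_px": np.round(stream.x_px, 2),
            "y_px": np.round(stream.y_px, 2),
            "valid": stream.valid.astype(int),
        }
    )
    if trial_idx is not None:
        df.insert(0, "trial_idx", trial_idx)
    df.to_csv(path, index=False)


def _stimulus_dict(stim: Stimulus) -> dict:
    return {
        "sf_cpd": stim.sf,
        "contrast": stim.contrast,
        "side": stim.side,
        "orientation_deg": stim.orientation,
    }


def write_trial_log(result: SessionResult, path: Union[str, Path]) -> None:
    """One JSON object per presented trial, in presentation order."""
    with open(path, "w") as fh:
        for rec in result.records:
            fh.write(
                json.dumps(
                    {
                        "trial_idx": rec.trial_idx,
                        "valid_idx": rec.valid_idx,
                        "stimulus": _stimulus_dict(rec.stimulus),
                        "outcome": rec.outcome,
                        "latency_ms": rec.latency_ms,
                        "posterior_entropy_bits": rec.posterior_entropy,
                        "cues": rec.cues,
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def read_trial_log(path: Union[str, Path]) -> List[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def write_session_summary(result: SessionResult, path: Union[str, Path]) -> None:
    est = result.estimate
    summary = {
        "protocol": result.protocol,
        "seed": result.seed,
        "complete": result.complete,
        "n_valid": result.n_valid,
        "n_invalid": result.n_invalid,
        "n_presented": result.n_presented,
        "cue_counts": {
            kind: sum(1 for c in result.cue_events if c.kind == kind)
            for kind in ("attention", "reward", "motivation", "bonus", "instruction")
        },
        "estimate": None
        if est is None
        else {
            "aulcsf_log10": est.aulcsf,
            "csf_acuity_logmar": est.csf_acuity_logmar,
            "param_means": est.param_means,
            "ci": {k: list(v) for k, v in est.ci.items()},
        },
    }
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


def write_paired_scores(pairs: PairedScores, path: Union[str, Path]) -> None:
    pd.DataFrame(
        {"subject_id": list(pairs.subject_ids), "test": pairs.test, "retest": pairs.retest}
    ).to_csv(path, index=False)


def read_paired_scores(
    path: Union[str, Path], label: str = "score", units: str = ""
) -> PairedScores:
    df = pd.read_csv(path)
    for col in ("subject_id", "test", "retest"):
        if col not in df.columns:
            raise ValueError(f"scores CSV {path} is missing required column {col!r}")
    return PairedScores(
        subject_ids=[str(s) for s in df["subject_id"]],
        test=df["test"].to_numpy(dtype=float),
        retest=df["retest"].to_numpy(dtype=float),
        label=label,
        units=units,
    )


def export_posterior(post: Posterior, path: Union[str, Path]) -> None:
    """Posterior snapshot as CSV: one row per grid point, four params + mass."""
    g = post.grid
    pd.DataFrame(
        {
            "gamma_max": g.gamma_max,
            "f_max_cpd": g.f_max,
            "beta_octaves": g.beta,
            "delta_log10": g.delta,
            "mass": post.mass,
        }
    ).to_csv(path, index=False)


def load_config(path: Union[str, Path]) -> dict:
    """Load a YAML or JSON config (JSON being a YAML subset, one loader)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


@dataclass
class RunManifest:
    """Everything needed to reproduce a CLI run bit-exactly."""

    command: str
    version: str
    seed: Optional[int]
    config: dict
    inputs: List[str]
    outputs: List[str]
    timestamp: str = ""
    config_hash: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime())
        if not self.config_hash:
            blob = json.dumps(self.config, sort_keys=True).encode()
            self.config_hash = hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(manifest: RunManifest, path: Union[str, Path]) -> None:
    Path(path).write_text(
        json.dumps(dataclasses.asdict(manifest), indent=2, sort_keys=True) + "\n"
    )
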