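"""Reading and writing recordings, event tables, estimates and reports.

Recordings are plain two-column TSV (time, conductance) or BIDS-style
physiological recordings (``*_physio.tsv.gz`` plus a JSON sidecar carrying
``SamplingFrequency``, ``StartTime`` and ``Columns``).  Event tables and
estimate tables are plain delimited text.  All event times are in seconds
from the first sample of the recording (``t0 = 0`` by default) and trial
windows are half-open ``[onset, next onset)``.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

__all__ = [
    "CS_PLUS",
    "CS_MINUS",
    "ScrRecording",
    "TrialEvent",
    "SessionDesign",
    "FormatError",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "write_estimates",
    "read_estimates",
]

CS_PLUS = "CS+"
CS_MINUS = "CS-"

#: accepted spellings for the two CS types in input tables
_CS_ALIASES = {
    "cs+": CS_PLUS, "csp": CS_PLUS, "cs_plus": CS_PLUS, "plus": CS_PLUS,
    "cs-": CS_MINUS, "cs−": CS_MINUS, "csm": CS_MINUS,
    "cs_minus": CS_MINUS, "minus": CS_MINUS,
}


class FormatError(ValueError):
    """An input file cannot be interpreted (missing rate, bad columns...)."""


@dataclass
class ScrRecording:
    """A uniformly sampled skin conductance trace.

    Parameters
    ----------
    values
        Conductance samples in microsiemens.
    rate
        Sampling frequency in Hz.
    t0
        Time of the first sample in seconds (0 by default).
    source_id
        Free-text provenance label.
    meta
        Provenance chain; processing stages append entries here.
    """

    values: np.ndarray
    rate: float
    t0: float = 0.0
    source_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("recording must be one-dimensional")
        if self.values.size < 2:
            raise ValueError("recording must contain at least 2 samples")
        if not self.rate > 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        bad = np.flatnonzero(~np.isfinite(self.values))
        if bad.size:
            raise ValueError(
                f"recording contains non-finite samples at indices {bad[:10].tolist()}"
                + ("..." if bad.size > 10 else "")
            )

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Time span covered, (n - 1) / rate seconds."""
        return (self.n - 1) / self.rate

    @property
    def times(self) -> np.ndarray:
        """Sample times; sample k sits at ``t0 + k / rate``."""
        return self.t0 + np.arange(self.n) / self.rate

    def with_values(self, values: np.ndarray, rate: float | None = None,
                    stage: str | None = None, **stage_info) -> "ScrRecording":
        """Copy of this recording with new samples and a provenance entry."""
        meta = dict(self.meta)
        if stage is not None:
            meta.setdefault("chain", [])
            meta["chain"] = list(meta["chain"]) + [{"stage": stage, **stage_info}]
        return ScrRecording(np.asarray(values, dtype=float),
                            rate if rate is not None else self.rate,
                            t0=self.t0, source_id=self.source_id, meta=meta)


@dataclass(frozen=True)
class TrialEvent:
    """One conditioning trial: CS onset, CS type, reinforcement."""

    cs_onset: float
    cs_type: str
    reinforced: bool = False
    participant_id: str = ""

    def __post_init__(self) -> None:
        if self.cs_type not in (CS_PLUS, CS_MINUS):
            raise ValueError(f"cs_type must be {CS_PLUS!r} or {CS_MINUS!r}, "
                             f"got {self.cs_type!r}")
        if self.reinforced and self.cs_type != CS_PLUS:
            raise ValueError(f"a {CS_MINUS} trial cannot be reinforced "
                             f"(onset {self.cs_onset} s)")


@dataclass
class SessionDesign:
    """The experimental timeline of one session.

    ``soa`` is the fixed CS-onset-to-US latency (3.5 s in the delay
    conditioning designs this package targets), ``cs_duration`` the CS
    presentation length, and ``evoked_dispersion`` the fixed width of the
    US-evoked sudomotor burst.
    """

    trials: list[TrialEvent]
    soa: float = 3.5
    cs_duration: float = 4.0
    evoked_dispersion: float = 0.3
    min_iti: float = 0.0

    def __post_init__(self) -> None:
        if not self.soa <= self.cs_duration:
            raise ValueError(f"soa ({self.soa}) must not exceed cs_duration "
                             f"({self.cs_duration})")
        onsets = [tr.cs_onset for tr in self.trials]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("trial onsets must be strictly increasing")
        gaps = np.diff(onsets)
        if gaps.size and gaps.min() < self.cs_duration + self.min_iti:
            raise ValueError("inter-onset gap shorter than cs_duration + min ITI")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([tr.cs_onset for tr in self.trials])

    @property
    def cs_types(self) -> list[str]:
        return [tr.cs_type for tr in self.trials]

    @property
    def reinforced(self) -> np.ndarray:
        return np.array([tr.reinforced for tr in self.trials], dtype=bool)

    def next_onset(self, i: int, default: float | None = None) -> float:
        """Onset of trial ``i + 1``; ``default`` past the last trial."""
        if i + 1 < self.n_trials:
            return self.trials[i + 1].cs_onset
        if default is None:
            raise IndexError(f"trial {i} has no successor")
        return default


# ---------------------------------------------------------------------------
# recordings

def read_recording(path: str | Path, format: str = "tsv",
                   channel: str | None = None) -> ScrRecording:
    """Read a conductance recording from ``tsv`` or ``bids_physio`` format.

    The plain format is a two-column delimited table (time in seconds,
    conductance in microsiemens); the sampling rate is inferred from the
    time column and must be uniform.  The BIDS format is a (gzipped)
    column table whose JSON sidecar declares ``SamplingFrequency``;
    units are converted to microsiemens when the sidecar declares ``S``
    or ``mS``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_tsv_recording(path)
    if format == "bids_physio":
        return _read_bids_recording(path, channel)
    raise FormatError(f"unknown recording format {format!r}")


def _read_tsv_recording(path: Path) -> ScrRecording:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (time, value)")
    t = df.iloc[:, 0].to_numpy(float)
    v = df.iloc[:, 1].to_numpy(float)
    if t.size < 2:
        raise FormatError(f"{path}: need at least two samples to infer rate")
    dt = np.diff(t)
    if dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise FormatError(f"{path}: time column is not uniformly increasing; "
                          "cannot infer a sampling rate")
    rate = 1.0 / float(np.median(dt))
    return ScrRecording(v, rate=rate, t0=float(t[0]), source_id=str(path))


_UNIT_TO_MICROSIEMENS = {
    "us": 1.0, "microsiemens": 1.0, "µs": 1.0, "μs": 1.0,
    "ms": 1e3, "millisiemens": 1e3,
    "s": 1e6, "siemens": 1e6,
}


def _read_bids_recording(path: Path, channel: str | None) -> ScrRecording:
    sidecar = path.with_suffix("").with_suffix("") if path.name.endswith(".tsv.gz") \
        else path.with_suffix("")
    sidecar = sidecar.parent / (sidecar.name + ".json")
    if not sidecar.exists():
        raise FormatError(f"{path}: missing JSON sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    if "SamplingFrequency" not in meta:
        raise FormatError(f"{sidecar}: sidecar lacks SamplingFrequency")
    rate = float(meta["SamplingFrequency"])
    opener = gzip.open if path.name.endswith(".gz") else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, sep="\t", header=None)
    cols = meta.get("Columns")
    if cols is not None:
        df.columns = cols
        if channel is None:
            channel = cols[0]
        if channel not in df.columns:
            raise FormatError(f"{path}: channel {channel!r} not in Columns {cols}")
        v = df[channel].to_numpy(float)
    else:
        v = df.iloc[:, 0].to_numpy(float)
    unit = str(meta.get("Units", meta.get("units", "uS"))).strip().lower()
    factor = _UNIT_TO_MICROSIEMENS.get(unit)
    if factor is None:
        raise FormatError(f"{sidecar}: unknown conductance unit {unit!r}")
    t0 = float(meta.get("StartTime", 0.0))
    return ScrRecording(v * factor, rate=rate, t0=t0, source_id=str(path))


def write_recording(rec: ScrRecording, path: str | Path) -> None:
    """Write a recording as two-column TSV (time, conductance)."""
    df = pd.DataFrame({"time": rec.times, "conductance": rec.values})
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# events

def read_events(path: str | Path, soa: float = 3.5, cs_duration: float = 4.0,
                evoked_dispersion: float = 0.3) -> SessionDesign:
    """Read a session event table (columns cs_onset, cs_type, reinforced)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"cs_onset", "cs_type", "reinforced"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if len(df) == 0:
        raise FormatError(f"{path}: no trials")
    trials = []
    for _, row in df.iterrows():
        cs = str(row["cs_type"]).strip()
        cs = _CS_ALIASES.get(cs.lower(), cs)
        trials.append(TrialEvent(
            cs_onset=float(row["cs_onset"]),
            cs_type=cs,
            reinforced=_as_bool(row["reinforced"]),
            participant_id=str(row.get("participant_id", "")),
        ))
    onsets = [tr.cs_onset for tr in trials]
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        raise FormatError(f"{path}: cs_onset column is not strictly increasing")
    return SessionDesign(trials, soa=soa, cs_duration=cs_duration,
                         evoked_dispersion=evoked_dispersion)


def _as_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in ("1", "true", "yes", "y")
    return bool(x)


def write_events(design: SessionDesign, path: str | Path) -> None:
    df = pd.DataFrame({
        "cs_onset": [tr.cs_onset for tr in design.trials],
        "cs_type": [tr.cs_type for tr in design.trials],
        "reinforced": [int(tr.reinforced) for tr in design.trials],
        "participant_id": [tr.participant_id for tr in design.trials],
    })
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# estimates

#: columns of the estimate table, one row per trial
ESTIMATE_COLUMNS = [
    "trial", "cs_type", "reinforced", "cs_onset",
    "amplitude", "onset", "duration", "evoked_amplitude",
    "objective", "converged",
]


def write_estimates(estimates, path: str | Path) -> None:
    """Write per-trial arousal estimates as TSV, one row per trial.

    Excluded trials keep their row with amplitude fields set to NaN, so
    the table always aligns with the session design.  Round-trips through
    :func:`read_estimates` losslessly at 1e-9.
    """
    df = estimates if isinstance(estimates, pd.DataFrame) else estimates.df
    out = df.reindex(columns=ESTIMATE_COLUMNS)
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_estimates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(ESTIMATE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing estimate columns {sorted(missing)}")
    return df
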