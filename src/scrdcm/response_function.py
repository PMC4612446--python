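"""Skin conductance response functions as third-order linear ODEs.

A response function (RF) maps sudomotor nerve activity ``u(t)`` to the
observable conductance change ``x(t)`` through

    x''' + a1 x'' + a2 x' + a3 x = b u(t).

Two RFs are supported: a fixed canonical RF (cRF) shipped with the package,
and an individual RF (iRF) estimated per participant from the first
principal component of post-US signal segments.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import optimize, signal

from .io import ScrRecording, SessionDesign

__all__ = [
    "OdeRF",
    "NoPeakError",
    "canonical_rf",
    "impulse_response",
    "estimate_individual_rf",
]


class NoPeakError(RuntimeError):
    """No identifiable peak in the first principal component.

    Callers should fall back to :func:`canonical_rf`.
    """


@dataclass(frozen=True)
class OdeRF:
    """Coefficients of ``x''' + a1 x'' + a2 x' + a3 x = b u(t)``."""

    a1: float
    a2: float
    a3: float
    b: float
    label: str = "canonical"
    provenance: str = ""

    @property
    def denominator(self) -> np.ndarray:
        return np.array([1.0, self.a1, self.a2, self.a3])

    @property
    def poles(self) -> np.ndarray:
        """Roots of the characteristic polynomial."""
        return np.roots(self.denominator)

    @property
    def is_stable(self) -> bool:
        return bool(np.all(self.poles.real < 0))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "OdeRF":
        d = json.loads(Path(path).read_text())
        return cls(**{k: d[k] for k in ("a1", "a2", "a3", "b")},
                   label=d.get("label", "individual"),
                   provenance=d.get("provenance", ""))


def canonical_rf() -> OdeRF:
    """The fixed canonical response function shipped with the package.

    Its impulse response is unimodal (single positive peak ~2.5 s after the
    impulse, unit peak height) with a slow decaying tail that falls below 1%
    of the peak within 25 s.
    """
    with resources.files("scrdcm.data").joinpath("canonical_rf.json").open() as fh:
        d = json.load(fh)
    return OdeRF(d["a1"], d["a2"], d["a3"], d["b"], label="canonical",
                 provenance=d.get("provenance", ""))


def impulse_response(rf: OdeRF, duration: float, rate: float) -> ScrRecording:
    """Impulse response of the RF: integrate the ODE from rest with a
    unit-area impulsive input, sampled at ``rate``."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not rf.is_stable:
        raise ValueError(f"unstable RF coefficients, poles {rf.poles}")
    t = np.arange(int(round(duration * rate))) / rate
    _, h = signal.impulse(signal.lti([rf.b], rf.denominator), T=t)
    return ScrRecording(h, rate=rate, source_id=f"impulse_response[{rf.label}]")


# ---------------------------------------------------------------------------
# individual RF estimation

def _first_component(segments: np.ndarray) -> np.ndarray:
    # dominant shared shape across trials: first right singular vector of the
    # (trials x samples) segment matrix, uncentred so the event-locked mean
    # response is retained
    _, _, vt = np.linalg.svd(segments, full_matrices=False)
    comp = vt[0]
    # sign so the peak is positive
    if -comp.min() > comp.max():
        comp = -comp
    return comp


def _interior_peak(comp: np.ndarray) -> int:
    """Index of an identifiable interior peak of the component, or raise.

    A peak qualifies when it is an interior local maximum whose height
    above the component median exceeds 3x the robust point-noise SD,
    estimated from the median absolute successive difference
    (MAD(diff)/(0.6745*sqrt(2))).  A smooth event-locked component passes
    easily; an unstructured (noise-dominated) or monotone component does
    not.
    """
    noise_sd = (np.median(np.abs(np.diff(comp))) / (0.6745 * math.sqrt(2.0))
                if comp.size > 1 else 0.0)
    thresh = np.median(comp) + 3.0 * max(noise_sd, 1e-12)
    interior = (np.r_[False, comp[1:] > comp[:-1]] &
                np.r_[comp[:-1] > comp[1:], False])
    candidates = np.flatnonzero(interior & (comp > thresh))
    if candidates.size == 0:
        raise NoPeakError("no identifiable peak in the first principal "
                          "component")
    return int(candidates[np.argmax(comp[candidates])])


def estimate_individual_rf(rec: ScrRecording, design: SessionDesign,
                           min_trials: int = 10) -> OdeRF:
    """Estimate an individual RF from a participant's recording.

    Per trial, the segment from the last evoked response (CS onset + SOA)
    to the next trial onset is extracted; all segments are truncated to the
    shortest window and variance-normalised so single high-amplitude trials
    cannot dominate.  The first principal component across segments is
    computed, its peak located, and a stable third-order ODE fitted to the
    peak-aligned component by least squares on the impulse response (free
    latency shift and offset; the fitted gain is normalised to unit peak,
    with overall gain absorbed downstream into amplitude estimates).

    Raises
    ------
    NoPeakError
        If the first component has no identifiable interior peak; callers
        should fall back to the canonical RF.
    """
    rate = rec.rate
    end_time = rec.t0 + rec.n / rate
    starts, stops = [], []
    for i, tr in enumerate(design.trials):
        t_start = tr.cs_onset + design.soa
        t_stop = design.next_onset(i, default=end_time)
        if t_stop <= t_start or t_stop > end_time + 1e-9:
            continue
        starts.append(t_start)
        stops.append(t_stop)
    if len(starts) < min_trials:
        raise ValueError(f"need >= {min_trials} trials with usable post-US "
                         f"windows, found {len(starts)}")
    n_win = int(min(b - a for a, b in zip(starts, stops)) * rate)
    if n_win < 4:
        raise ValueError("post-US windows too short to estimate an RF")
    rows = []
    for t_start in starts:
        i0 = int(round((t_start - rec.t0) * rate))
        seg = rec.values[i0:i0 + n_win]
        sd = seg.std(ddof=1)
        if sd > 0:
            rows.append((seg - seg.mean()) / sd)
    if len(rows) < min_trials:
        raise ValueError("too many degenerate (constant) post-US segments")
    comp = _first_component(np.asarray(rows))
    peak_idx = _interior_peak(comp)

    target = comp / comp[peak_idx]  # peak-normalised
    t = np.arange(n_win) / rate
    t_peak = t[peak_idx]

    def model(params: np.ndarray) -> np.ndarray:
        log_taus, gain, shift, offset = params[:3], params[3], params[4], params[5]
        a = np.poly(-1.0 / np.exp(log_taus))
        tt = np.arange(n_win + int(4 * rate)) / rate
        _, h = signal.impulse(signal.lti([1.0], a), T=tt)
        return gain * np.interp(t + shift, tt, h, left=0.0) + offset

    x0 = np.r_[np.log([0.7, 0.7, 4.3]), 1.0, 2.0, 0.0]
    lb = np.r_[np.log([0.2, 0.2, 0.2]), -np.inf, 0.0, -np.inf]
    ub = np.r_[np.log([15.0, 15.0, 15.0]), np.inf, max(t_peak, 0.5), np.inf]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol = optimize.least_squares(lambda p: model(p) - target, x0,
                                     bounds=(lb, ub), max_nfev=200)
    taus = np.exp(sol.x[:3])
    a = np.poly(-1.0 / taus)
    # normalise gain so the impulse response peaks at 1
    tt = np.arange(int(60 * rate)) / rate
    _, h = signal.impulse(signal.lti([1.0], a), T=tt)
    if h.max() <= 0:
        raise NoPeakError("fitted impulse response has no positive peak")
    rf = OdeRF(a[1], a[2], a[3], b=1.0 / h.max(), label="individual",
               provenance=f"fit from {len(rows)} post-US segments, "
                          f"taus={np.round(taus, 4).tolist()}")
    if not rf.is_stable:  # unreachable with the tau parameterisation, kept as a guard
        raise NoPeakError("fitted RF is unstable")
    return rf
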