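"""Generative forward model: sudomotor bursts to predicted skin conductance.

Per trial, sudomotor input is a sum of Gaussian bursts:

* one anticipatory burst with free amplitude, onset (constrained to the
  CS-onset-to-US window) and dispersion,
* one US-evoked burst at CS onset + SOA with free amplitude and fixed
  dispersion,
* optional spontaneous-fluctuation (SF) bursts confined to the inter-trial
  interval.

Burst amplitude is parameterised as the Gaussian *peak height* (not area),
so amplitudes stay comparable across dispersions.  The summed input drives
the third-order response-function ODE; an optional tonic skin conductance
level (SCL) component adds a piecewise-linear baseline with one node per
trial onset (increments given per trial), smoothed by a first-order lag
with a 30 s time constant so it stays spectrally disjoint from phasic
responses.

Integration uses a fixed-step classical 4th-order scheme at 10x the output
rate (input evaluated on the half-step grid), realised as a vectorised
linear recursion, then decimated to the output rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io import ScrRecording, SessionDesign
from .response_function import OdeRF

__all__ = [
    "BurstParams",
    "TrialParams",
    "SCL_LAG_TAU",
    "sudomotor_input",
    "scl_drift",
    "predict_scr",
]

#: time constant (s) of the first-order lag smoothing the SCL baseline
SCL_LAG_TAU = 30.0

#: internal integration runs at this multiple of the output rate
OVERSAMPLE = 10


@dataclass
class BurstParams:
    """A Gaussian sudomotor burst: peak height, centre (s), SD (s)."""

    amplitude: float
    onset: float
    dispersion: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"burst amplitude must be >= 0, got {self.amplitude}")
        if not self.dispersion > 0:
            raise ValueError(f"burst dispersion must be > 0, got {self.dispersion}")


@dataclass
class TrialParams:
    """Per-trial burst parameters (ground truth or estimates)."""

    anticipatory: BurstParams
    evoked_amplitude: float = 0.0
    sf: list[BurstParams] = field(default_factory=list)
    scl_change: float = 0.0

    def __post_init__(self) -> None:
        if self.evoked_amplitude < 0:
            raise ValueError("evoked amplitude must be >= 0")


def _validate(params: list[TrialParams], design: SessionDesign) -> None:
    if len(params) != design.n_trials:
        raise ValueError(f"{len(params)} parameter sets for {design.n_trials} trials")
    tol = 1e-9
    for i, (tp, tr) in enumerate(zip(params, design.trials)):
        lo, hi = tr.cs_onset, tr.cs_onset + design.soa
        if not (lo - tol <= tp.anticipatory.onset <= hi + tol):
            raise ValueError(
                f"trial {i}: anticipatory onset {tp.anticipatory.onset} outside "
                f"[{lo}, {hi}]")
        sf_lo = tr.cs_onset + design.cs_duration
        sf_hi = design.next_onset(i, default=np.inf)
        for b in tp.sf:
            if not (sf_lo - tol <= b.onset < sf_hi + tol):
                raise ValueError(
                    f"trial {i}: SF onset {b.onset} outside ITI [{sf_lo}, {sf_hi})")


def _all_bursts(params: list[TrialParams], design: SessionDesign):
    for tp, tr in zip(params, design.trials):
        if tp.anticipatory.amplitude > 0:
            yield tp.anticipatory
        if tp.evoked_amplitude > 0:
            yield BurstParams(tp.evoked_amplitude, tr.cs_onset + design.soa,
                              design.evoked_dispersion)
        yield from (b for b in tp.sf if b.amplitude > 0)


def _add_bursts(out: np.ndarray, t0: float, rate: float, bursts) -> np.ndarray:
    """Accumulate Gaussian bursts onto a sample grid (support +-6 SD)."""
    n = out.size
    for b in bursts:
        i0 = max(0, int(np.floor((b.onset - 6 * b.dispersion - t0) * rate)))
        i1 = min(n, int(np.ceil((b.onset + 6 * b.dispersion - t0) * rate)) + 1)
        if i1 <= i0:
            continue
        tt = t0 + np.arange(i0, i1) / rate
        out[i0:i1] += b.amplitude * np.exp(-0.5 * ((tt - b.onset) / b.dispersion) ** 2)
    return out


def sudomotor_input(params: list[TrialParams], design: SessionDesign,
                    rate: float, duration: float | None = None,
                    t0: float = 0.0) -> ScrRecording:
    """Summed Gaussian sudomotor input over the session, sampled at ``rate``."""
    _validate(params, design)
    if duration is None:
        duration = design.onsets[-1] + 30.0 - t0
    n = int(round(duration * rate))
    u = _add_bursts(np.zeros(n), t0, rate, _all_bursts(params, design))
    return ScrRecording(u, rate=rate, t0=t0, source_id="sudomotor_input")


def scl_drift(params: list[TrialParams], design: SessionDesign, rate: float,
              n: int, t0: float = 0.0) -> np.ndarray:
    """Tonic SCL component: lag-smoothed piecewise-linear baseline.

    The target level ramps by ``scl_change`` of trial k between the onsets
    of trials k and k+1 (the last ramp reuses the preceding inter-onset
    gap), then a first-order lag with time constant :data:`SCL_LAG_TAU`
    smooths the result.
    """
    t = t0 + np.arange(n) / rate
    onsets = design.onsets
    changes = np.array([tp.scl_change for tp in params])
    gaps = np.diff(onsets)
    last_gap = gaps[-1] if gaps.size else 10.0
    node_t = np.r_[t[0], onsets, onsets[-1] + last_gap]
    node_v = np.r_[0.0, 0.0, np.cumsum(changes)]
    target = np.interp(t, node_t, node_v)
    alpha = 1.0 - np.exp(-1.0 / (rate * SCL_LAG_TAU))
    return signal.lfilter([alpha], [1.0, -(1.0 - alpha)], target)


def _rk4_filter_response(rf: OdeRF, u_half: np.ndarray, h: float,
                         n_out: int) -> np.ndarray:
    """Integrate the RF ODE with the classical 4th-order scheme.

    ``u_half`` holds the input on the half-step grid (spacing h/2).  For a
    linear time-invariant system the RK4 update is an exact linear
    recursion in the state, which is evaluated here with three ``lfilter``
    passes (one per input tap: step start, midpoint, step end).
    """
    A = np.array([[0.0, 1.0, 0.0],
                  [0.0, 0.0, 1.0],
                  [-rf.a3, -rf.a2, -rf.a1]])
    B = np.array([0.0, 0.0, rf.b])
    C = np.array([[1.0, 0.0, 0.0]])
    I = np.eye(3)
    hA = h * A
    hA2, hA3, hA4 = hA @ hA, None, None
    hA3 = hA2 @ hA
    hA4 = hA3 @ hA
    M = I + hA + hA2 / 2 + hA3 / 6 + hA4 / 24
    G0 = (h / 6.0) * (I + hA + hA2 / 2 + hA3 / 4) @ B
    Gm = (h / 6.0) * (4 * I + 2 * hA + hA2 / 2) @ B
    G1 = (h / 6.0) * B

    idx = 2 * np.arange(n_out)
    last = u_half.size - 1
    taps = (u_half[np.minimum(idx, last)],
            u_half[np.minimum(idx + 1, last)],
            u_half[np.minimum(idx + 2, last)])
    y = np.zeros(n_out)
    for G, w in zip((G0, Gm, G1), taps):
        num, den = signal.ss2tf(M, G.reshape(3, 1), C, [[0.0]])
        y += signal.lfilter(num[0], den, w)
    return y


def predict_scr(params: list[TrialParams], design: SessionDesign, rf: OdeRF,
                rate: float, include_scl: bool = True, baseline: float = 0.0,
                duration: float | None = None, t0: float = 0.0) -> ScrRecording:
    """Predicted conductance trace for a session.

    Integrates the RF ODE driven by :func:`sudomotor_input` with a fixed-step
    4th-order scheme at 10x the output rate, then decimates.  When
    ``include_scl`` the lag-smoothed SCL drift is added on top of the
    constant ``baseline``; otherwise the baseline alone is used ("SCL is
    computed for the first trial and assumed constant").
    """
    _validate(params, design)
    if not rf.is_stable:
        raise ValueError(f"unstable RF coefficients, poles {rf.poles}")
    if duration is None:
        duration = design.onsets[-1] + 30.0 - t0
    n_out = int(round(duration * rate))
    h = 1.0 / (OVERSAMPLE * rate)
    n_fine = OVERSAMPLE * (n_out - 1) + 1
    n_half = 2 * (n_fine - 1) + 1
    u_half = _add_bursts(np.zeros(n_half), t0, 2.0 / h,
                         _all_bursts(params, design))
    y_fine = _rk4_filter_response(rf, u_half, h, n_fine)
    y = y_fine[::OVERSAMPLE]
    y = np.r_[y, np.full(n_out - y.size, y[-1])] if y.size < n_out else y[:n_out]
    y = y + baseline
    if include_scl:
        y = y + scl_drift(params, design, rate, n_out, t0)
    return ScrRecording(y, rate=rate, t0=t0, source_id="predict_scr")
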