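"""Preprocessing chain for skin conductance recordings.

The chain, applied in order by :func:`preprocess_pipeline`:

1. optional median despiking (for MRI gradient artefacts),
2. low-pass filtering (first-order Butterworth, 5 Hz),
3. downsampling to 10 Hz,
4. high-pass filtering (first-order Butterworth applied twice, either
   forward+backward — "bi-directional", zero net phase — or twice forward,
   "uni-directional"),
5. normalisation (subtract the minimum, divide by the sample SD).

Because the high-pass stage applies the first-order filter twice in either
direction, uni- and bi-directional filtering share the same magnitude
response (amplitude 1/2 at the cutoff frequency) and differ only in phase:
the bi-directional variant preserves peak latencies while the uni-directional
variant shifts peaks in time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .io import ScrRecording

__all__ = [
    "FilterSpec",
    "HP_CUTOFF_PRESETS",
    "DEFAULT_HP",
    "median_despike",
    "butter_filter",
    "resample_to",
    "normalise",
    "preprocess_pipeline",
]

#: candidate high-pass cutoffs (Hz); 0.0159 Hz (10 s time constant) is the default
HP_CUTOFF_PRESETS = (0.005, 0.01, 0.0159, 0.035, 0.05, 0.06)


@dataclass(frozen=True)
class FilterSpec:
    """A Butterworth filter stage.

    ``direction`` is meaningful for high-pass filters only: ``"bi"`` runs the
    filter forward then backward, ``"uni"`` runs it forward twice.
    """

    kind: str  # "lowpass" | "highpass"
    cutoff: float  # Hz
    order: int = 1
    direction: str | None = None  # "uni" | "bi", highpass only

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "highpass"):
            raise ValueError(f"kind must be 'lowpass' or 'highpass', got {self.kind!r}")
        if not self.cutoff > 0:
            raise ValueError("cutoff must be positive")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.kind == "highpass":
            if self.direction not in ("uni", "bi"):
                raise ValueError("highpass filters need direction 'uni' or 'bi'")
        elif self.direction is not None:
            raise ValueError("direction is defined only for highpass filters")


DEFAULT_HP = FilterSpec("highpass", 0.0159, order=1, direction="bi")


def median_despike(rec: ScrRecording, n_neighbours: int = 10) -> ScrRecording:
    """Replace each sample by the median over itself and its neighbours.

    The window is centred and has length ``n_neighbours + 1``; windows are
    truncated at the edges.  Removes brief artefact spikes (e.g. 2 ms MRI
    gradient spikes at 1000 Hz) while leaving locally monotone data intact.
    """
    if n_neighbours < 2 or n_neighbours % 2:
        raise ValueError(f"n_neighbours must be even and >= 2, got {n_neighbours}")
    win = n_neighbours + 1
    if rec.n <= win:
        raise ValueError(f"recording ({rec.n} samples) shorter than the "
                         f"despike window ({win})")
    out = (pd.Series(rec.values)
           .rolling(win, center=True, min_periods=1)
           .median()
           .to_numpy())
    return rec.with_values(out, stage="median_despike", n_neighbours=n_neighbours)


def _pad_reflect(x: np.ndarray, pad: int) -> np.ndarray:
    # odd reflection at both ends suppresses startup transients
    return np.pad(x, pad, mode="reflect", reflect_type="odd")


def _transient_pad(rec_rate: float, cutoff: float, n: int) -> int:
    # three filter time constants, capped below the signal length
    pad = int(math.ceil(3.0 * rec_rate / (2.0 * math.pi * cutoff)))
    return min(pad, n - 1)


def butter_filter(rec: ScrRecording, spec: FilterSpec) -> ScrRecording:
    """Apply a Butterworth filter stage.

    Low-pass: a single forward pass of the stated order.  High-pass: the
    filter is applied twice — forward then backward for ``direction="bi"``
    (zero net phase), forward twice for ``direction="uni"``.  Both ends are
    padded by odd reflection over three filter time constants before
    filtering to minimise startup transients; output length equals input
    length.
    """
    nyq = rec.rate / 2.0
    if spec.cutoff >= nyq:
        raise ValueError(f"cutoff {spec.cutoff} Hz >= Nyquist {nyq} Hz")
    b, a = signal.butter(spec.order, spec.cutoff, btype=spec.kind, fs=rec.rate)
    pad = _transient_pad(rec.rate, spec.cutoff, rec.n)
    x = _pad_reflect(rec.values, pad)
    zi = signal.lfilter_zi(b, a)

    def one_pass(v):
        # start each pass at its step steady state to kill the residual
        # startup transient the reflect padding alone leaves behind
        out, _ = signal.lfilter(b, a, v, zi=zi * v[0])
        return out

    if spec.kind == "lowpass":
        y = one_pass(x)
    elif spec.direction == "uni":
        y = one_pass(one_pass(x))
    else:  # bi: forward, then backward
        y = one_pass(one_pass(x)[::-1])[::-1]
    out = y[pad:x.size - pad] if pad else y
    return rec.with_values(out, stage="butter", kind=spec.kind,
                           cutoff=spec.cutoff, order=spec.order,
                           direction=spec.direction)


def resample_to(rec: ScrRecording, target_rate: float = 10.0) -> ScrRecording:
    """Downsample to ``target_rate``.

    Decimation (every k-th sample) when the rate is an integer multiple of
    the target, linear interpolation onto the target grid otherwise.
    Assumes anti-alias low-pass filtering has been applied upstream.
    """
    if target_rate > rec.rate:
        raise ValueError(f"cannot upsample from {rec.rate} to {target_rate} Hz")
    if target_rate == rec.rate:
        return rec
    factor = rec.rate / target_rate
    if abs(factor - round(factor)) < 1e-9:
        out = rec.values[::int(round(factor))]
    else:
        t_new = rec.t0 + np.arange(int(np.floor(rec.duration * target_rate)) + 1) / target_rate
        out = np.interp(t_new, rec.times, rec.values)
    return rec.with_values(out, rate=target_rate, stage="resample",
                           target_rate=target_rate)


def normalise(rec: ScrRecording) -> ScrRecording:
    """Subtract the minimum and divide by the sample SD (n − 1 denominator).

    Removes inter-individual differences from peripheral factors of no
    interest; the output has minimum 0 and sample SD 1.
    """
    sd = float(np.std(rec.values, ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError("degenerate recording: zero variance, cannot normalise")
    out = (rec.values - rec.values.min()) / sd
    return rec.with_values(out, stage="normalise")


def preprocess_pipeline(rec: ScrRecording, hp: FilterSpec = DEFAULT_HP,
                        despike: bool = False, lp_cutoff: float = 5.0,
                        target_rate: float = 10.0) -> ScrRecording:
    """Run the full preprocessing chain.

    Order: optional median despike → low-pass (first order, 5 Hz) →
    downsample to 10 Hz → high-pass per ``hp`` → normalise.  The chain is
    recorded in the output's provenance metadata.  Despiking is intended
    for MRI-contaminated recordings only.
    """
    if hp.kind != "highpass":
        raise ValueError("hp must be a highpass FilterSpec")
    out = rec
    if despike:
        out = median_despike(out)
    if lp_cutoff < out.rate / 2.0:
        out = butter_filter(out, FilterSpec("lowpass", lp_cutoff, order=1))
    out = resample_to(out, target_rate)
    out = butter_filter(out, hp)
    out = normalise(out)
    return out
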