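"""Conventional trough-to-peak scoring of anticipatory SCR.

The classical benchmark the model-based estimator is compared against: a
response onset (trough followed by a sustained rise) is sought in a window
1–4.5 s after CS onset; the peak is the maximum in a second window 0.5–5 s
after that onset; the amplitude is the baseline-corrected peak height.
Trials without a qualifying onset score zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ScrRecording, SessionDesign, CS_PLUS, CS_MINUS

__all__ = ["PeakScore", "peak_score_trial", "peak_score_session"]

#: onset search window relative to CS onset (s)
ONSET_WINDOW = (1.0, 4.5)
#: peak search window relative to the response onset (s)
PEAK_WINDOW = (0.5, 5.0)
#: the first derivative must stay positive this long to count as a rise (s)
MIN_RISE = 0.3


@dataclass(frozen=True)
class PeakScore:
    """Per-trial trough-to-peak score; times in seconds, absolute."""

    onset: float | None
    peak: float | None
    amplitude: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.onset is not None and self.peak is not None:
            if self.peak < self.onset + PEAK_WINDOW[0]:
                raise ValueError("peak latency must be >= onset + 0.5 s")


def peak_score_trial(rec: ScrRecording, cs_onset: float) -> PeakScore:
    """Score one trial of a (preprocessed) recording.

    The response onset is the first sample in [cs_onset+1, cs_onset+4.5]
    where the first derivative turns positive and stays positive for at
    least 0.3 s (the trough serves as baseline); the peak is the maximum
    in [onset+0.5, onset+5].  Returns amplitude 0 when no onset qualifies.
    """
    rate = rec.rate
    end_time = rec.t0 + (rec.n - 1) / rate
    if cs_onset + ONSET_WINDOW[1] + PEAK_WINDOW[1] > end_time + 1e-9:
        raise ValueError(
            f"recording ends at {end_time:.2f} s; trial at {cs_onset:.2f} s "
            f"needs coverage to {cs_onset + 9.5:.2f} s")
    x = rec.values
    i_lo = int(np.ceil((cs_onset + ONSET_WINDOW[0] - rec.t0) * rate))
    i_hi = int(np.floor((cs_onset + ONSET_WINDOW[1] - rec.t0) * rate))
    n_rise = max(1, int(round(MIN_RISE * rate)))
    dv = np.diff(x)
    rising = dv > 0
    onset_idx = None
    for i in range(i_lo, i_hi + 1):
        if rising[i:i + n_rise].size == n_rise and rising[i:i + n_rise].all():
            onset_idx = i
            break
    if onset_idx is None:
        return PeakScore(None, None, 0.0)
    t_on = rec.t0 + onset_idx / rate
    j_lo = int(np.ceil((t_on + PEAK_WINDOW[0] - rec.t0) * rate))
    j_hi = min(int(np.floor((t_on + PEAK_WINDOW[1] - rec.t0) * rate)), x.size - 1)
    j_peak = j_lo + int(np.argmax(x[j_lo:j_hi + 1]))
    amp = max(float(x[j_peak] - x[onset_idx]), 0.0)
    return PeakScore(t_on, rec.t0 + j_peak / rate, amp)


def peak_score_session(rec: ScrRecording, design: SessionDesign
                       ) -> tuple[list[PeakScore], dict]:
    """Score every trial; mean amplitude per CS type excludes reinforced
    CS+ trials (US responses would confound the anticipatory score).

    A CS-type cell emptied by the exclusion yields a ``None`` mean.
    """
    scores = [peak_score_trial(rec, tr.cs_onset) for tr in design.trials]
    means = {}
    for cs in (CS_PLUS, CS_MINUS):
        amps = [s.amplitude for s, tr in zip(scores, design.trials)
                if tr.cs_type == cs and not tr.reinforced]
        means[cs] = float(np.mean(amps)) if amps else None
    return scores, means


def scores_to_frame(scores: list[PeakScore], design: SessionDesign
                    ) -> pd.DataFrame:
    """Tabulate per-trial peak scores in the estimate-table layout."""
    return pd.DataFrame({
        "trial": np.arange(design.n_trials),
        "cs_type": design.cs_types,
        "reinforced": design.reinforced.astype(int),
        "cs_onset": design.onsets,
        "amplitude": [s.amplitude for s in scores],
        "onset": [s.onset if s.onset is not None else np.nan for s in scores],
        "duration": np.nan,
        "evoked_amplitude": np.nan,
        "objective": np.nan,
        "converged": 1,
    })
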