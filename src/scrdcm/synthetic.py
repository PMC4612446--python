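"""Synthetic fear-conditioning sessions with known ground truth.

Emulates the delay-conditioning designs this package targets: 4 s CS, US
or omission 3.5 s after CS onset, inter-trial intervals drawn from a small
set of values, 50% CS+ of which 50% are reinforced.  Every stage of the
pipeline is testable against the serialised ground-truth burst parameters.

Trial-to-trial onset jitter of the anticipatory burst is the central lever:
an unknown, variable anticipatory latency is precisely what defeats
fixed-latency scoring methods.  A log-normal per-participant gain emulates
peripheral amplitude differences (electrode contact, skin properties) and
makes the benefit of within-participant z-standardisation visible.

All draws come from seeded generators with per-participant sub-streams
(``SeedSequence([seed, participant])``); no global random state is touched.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .io import ScrRecording, SessionDesign, TrialEvent, CS_PLUS, CS_MINUS
from .forward_model import BurstParams, TrialParams, predict_scr
from .response_function import canonical_rf

__all__ = ["CohortSpec", "CohortData", "generate_session", "generate_cohort"]

#: peak conductance response to a unit-amplitude anticipatory burst
#: (dispersion 0.3 s) under the canonical RF; reference for the noise scale
UNIT_BURST_PEAK = 0.744


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults follow the 90-trials-per-type design with ITIs of 7–11 s;
    ``noise_sd`` defaults to 10% of the peak response to a mean CS+ burst.
    """

    n_participants: int = 20
    trials_per_type: int = 90
    cs_duration: float = 4.0
    soa: float = 3.5
    iti_choices: tuple = (7.0, 8.0, 9.0, 10.0, 11.0)
    reinforcement_rate: float = 0.5
    effect_cs_plus: float = 1.0          # mean anticipatory amplitude, CS+
    effect_cs_minus: float = 0.3         # mean anticipatory amplitude, CS−
    amplitude_sd: float = 0.3            # within-type amplitude SD
    onset_jitter_sd: float = 0.8         # anticipatory onset jitter (s)
    dispersion_mean: float = 0.3         # anticipatory burst width (s)
    dispersion_sd: float = 0.1
    evoked_mean: float = 1.0             # US-evoked burst amplitude
    evoked_sd: float = 0.3
    sf_rate_per_min: float = 4.0         # spontaneous fluctuations per minute
    sf_amplitude_scale: float = 0.15     # exponential SF amplitude scale
    scl_drift_sd: float = 0.05           # per-trial tonic increment SD (uS)
    noise_sd: float = 0.1 * UNIT_BURST_PEAK  # white measurement noise (uS)
    gain_sd: float = 0.5                 # log-normal participant gain SD
    baseline: float = 2.0                # tonic level (uS)
    rate: float = 100.0                  # recording sampling rate (Hz)
    lead_in: float = 10.0                # quiet time before the first CS (s)
    tail: float = 20.0                   # quiet time after the last CS (s)
    seed: int = 0
    design_seed: int | None = None       # share to fix the trial skeleton

    def __post_init__(self) -> None:
        if not (self.effect_cs_plus >= self.effect_cs_minus >= 0):
            raise ValueError("need effect(CS+) >= effect(CS-) >= 0")
        for name in ("amplitude_sd", "onset_jitter_sd", "sf_rate_per_min",
                     "scl_drift_sd", "noise_sd", "gain_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.iti_choices) + self.cs_duration <= self.cs_duration:
            raise ValueError("ITI choices must be positive")
        if min(self.iti_choices) <= 0:
            raise ValueError("impossible design: ITI must exceed 0")

    def spec_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class CohortData:
    sessions: list  # (ScrRecording, SessionDesign, list[TrialParams]) triples
    manifest: dict


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size=None) -> np.ndarray:
    """Truncated normal by rejection (vectorised, falls back to clipping)."""
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi)) if size else float(np.clip(mean, lo, hi))
    x = rng.normal(mean, sd, size=size)
    for _ in range(100):
        bad = (x < lo) | (x > hi)
        if not np.any(bad):
            break
        x = np.where(bad, rng.normal(mean, sd, size=np.shape(x)), x)
    return np.clip(x, lo, hi)


def _design_skeleton(spec: CohortSpec, rng: np.random.Generator,
                     participant: int) -> SessionDesign:
    n = 2 * spec.trials_per_type
    types = np.array([CS_PLUS] * spec.trials_per_type +
                     [CS_MINUS] * spec.trials_per_type)
    rng.shuffle(types)
    plus_idx = np.flatnonzero(types == CS_PLUS)
    n_reinf = int(round(spec.reinforcement_rate * plus_idx.size))
    reinf_idx = set(rng.choice(plus_idx, size=n_reinf, replace=False).tolist())
    itis = rng.choice(np.asarray(spec.iti_choices, dtype=float), size=n)
    trials = []
    t = spec.lead_in
    for i in range(n):
        trials.append(TrialEvent(t, str(types[i]), reinforced=i in reinf_idx,
                                 participant_id=f"sub-{participant:02d}"))
        t += spec.cs_duration + itis[i]
    return SessionDesign(trials, soa=spec.soa, cs_duration=spec.cs_duration)


def generate_session(spec: CohortSpec, participant: int
                     ) -> tuple[ScrRecording, SessionDesign, list[TrialParams]]:
    """One participant's recording, design, and ground-truth parameters.

    The trial skeleton (order, reinforcement, ITIs) is drawn from the
    design sub-stream; burst parameters and noise from the main sub-stream.
    Passing the same ``design_seed`` across specs keeps the skeleton fixed
    while everything else varies.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, participant]))
    design_seed = spec.seed if spec.design_seed is None else spec.design_seed
    design_rng = np.random.default_rng(
        np.random.SeedSequence([design_seed, participant, 1]))
    design = _design_skeleton(spec, design_rng, participant)

    gain = float(np.exp(rng.normal(0.0, spec.gain_sd))) if spec.gain_sd else 1.0
    effects = {CS_PLUS: spec.effect_cs_plus, CS_MINUS: spec.effect_cs_minus}
    truth: list[TrialParams] = []
    end_time = design.onsets[-1] + spec.cs_duration + spec.tail
    for i, tr in enumerate(design.trials):
        amp = _truncnorm(rng, effects[tr.cs_type], spec.amplitude_sd, 0.0, np.inf)
        onset = _truncnorm(rng, tr.cs_onset + spec.soa / 2.0,
                           spec.onset_jitter_sd, tr.cs_onset,
                           tr.cs_onset + spec.soa)
        disp = _truncnorm(rng, spec.dispersion_mean, spec.dispersion_sd,
                          0.1, 1.0)
        evoked = (_truncnorm(rng, spec.evoked_mean, spec.evoked_sd, 0.0, np.inf)
                  if tr.reinforced else 0.0)
        sf = []
        iti_lo = tr.cs_onset + spec.cs_duration
        iti_hi = design.next_onset(i, default=end_time)
        n_sf = rng.poisson(spec.sf_rate_per_min * (iti_hi - iti_lo) / 60.0)
        for _ in range(n_sf):
            sf.append(BurstParams(
                amplitude=gain * float(rng.exponential(spec.sf_amplitude_scale)),
                onset=float(rng.uniform(iti_lo + 0.3, iti_hi - 0.3)),
                dispersion=spec.dispersion_mean,
            ))
        truth.append(TrialParams(
            anticipatory=BurstParams(gain * float(amp), float(onset), float(disp)),
            evoked_amplitude=gain * float(evoked),
            sf=sf,
            scl_change=gain * float(rng.normal(0.0, spec.scl_drift_sd))
            if spec.scl_drift_sd else 0.0,
        ))
    duration = design.onsets[-1] + spec.cs_duration + spec.tail
    rec = predict_scr(truth, design, canonical_rf(), rate=spec.rate,
                      include_scl=True, baseline=spec.baseline,
                      duration=duration)
    if spec.noise_sd > 0:
        rec = rec.with_values(rec.values + rng.normal(0.0, spec.noise_sd, rec.n),
                              stage="measurement_noise", sd=spec.noise_sd)
    rec.source_id = f"synthetic/sub-{participant:02d}"
    return rec, design, truth


def generate_cohort(spec: CohortSpec) -> CohortData:
    """One session per participant plus a reproducibility manifest."""
    sessions = [generate_session(spec, p) for p in range(spec.n_participants)]
    manifest = {
        "spec": asdict(spec),
        "spec_hash": spec.spec_hash(),
        "participants": [f"sub-{p:02d}" for p in range(spec.n_participants)],
        "seeds": [[spec.seed, p] for p in range(spec.n_participants)],
        "files": [],
    }
    return CohortData(sessions, manifest)
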