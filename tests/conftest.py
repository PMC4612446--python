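"""Shared fixtures.

The cohort study fixture runs the complete pipeline (generate → preprocess
→ invert / peak-score) over replicate synthetic cohorts once per test
session; the predictive-validity and z-standardisation checks all consume
it.  Problem sizes follow the synthetic study conditions: 20 participants,
40 trials per session (20 per CS type), 10 replicate cohorts.
"""

from __future__ import annotations

import numpy as np
import pytest

from scrdcm import (CohortSpec, generate_cohort, generate_session,
                    InversionOptions, canonical_rf, preprocess_pipeline,
                    analyse_session_dcm, analyse_session_peak,
                    invert_session)

N_COHORTS = 10
COHORT_SEED = 1000
RECOVERY_SEED = 2000
N_RECOVERY_SESSIONS = 20


@pytest.fixture(scope="session")
def crf():
    return canonical_rf()


@pytest.fixture(scope="session")
def small_session():
    """A quick deterministic noiseless session at 10 Hz (6 trials)."""
    spec = CohortSpec(trials_per_type=3, noise_sd=0.0, sf_rate_per_min=0.0,
                      scl_drift_sd=0.0, gain_sd=0.0, rate=10.0, seed=7)
    return generate_session(spec, 0)


@pytest.fixture(scope="session")
def cohort_study():
    """Replicate cohorts pushed through the full pipeline.

    Returns a list of dicts per cohort with the session designs, ground
    truth, model-based (DCM) estimates and peak-scoring estimates.
    """
    results = []
    for c in range(N_COHORTS):
        spec = CohortSpec(n_participants=20, trials_per_type=20,
                          seed=COHORT_SEED + c)
        cohort = generate_cohort(spec)
        designs, truths, dcm, peak = [], [], [], []
        for rec, design, truth in cohort.sessions:
            pre = preprocess_pipeline(rec)
            dcm.append(analyse_session_dcm(pre, design, preprocessed=True))
            peak.append(analyse_session_peak(pre, design, preprocessed=True))
            designs.append(design)
            truths.append(truth)
        results.append({"designs": designs, "truths": truths,
                        "dcm": dcm, "peak": peak})
    return results


@pytest.fixture(scope="session")
def recovery_study(crf):
    """Parameter-recovery runs: one noiseless session inverted directly at
    10 Hz, plus noisy 40-trial sessions through the preprocessing chain."""
    spec0 = CohortSpec(trials_per_type=20, noise_sd=0.0, sf_rate_per_min=0.0,
                       scl_drift_sd=0.0, gain_sd=0.0, rate=10.0, seed=42)
    rec, design, truth = generate_session(spec0, 0)
    est = invert_session(rec, design, crf, InversionOptions())
    noiseless = {"design": design, "truth": truth, "est": est}

    true_amp, est_amp = [], []
    for s in range(N_RECOVERY_SESSIONS):
        spec = CohortSpec(trials_per_type=20, gain_sd=0.0,
                          seed=RECOVERY_SEED + s)
        rec, design, truth = generate_session(spec, 0)
        pre = preprocess_pipeline(rec)
        est = invert_session(pre, design, crf, InversionOptions())
        true_amp += [tp.anticipatory.amplitude for tp in truth]
        est_amp += list(est.sa)
    noisy = {"true_amp": np.asarray(true_amp), "est_amp": np.asarray(est_amp)}
    return {"noiseless": noiseless, "noisy": noisy}
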