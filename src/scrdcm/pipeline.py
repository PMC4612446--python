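"""High-level convenience pipeline: preprocess → estimate → evaluate.

Thin glue over the module layer, used by the command-line interface and
the evaluation scripts.
"""

from __future__ import annotations

import logging

import pandas as pd

from .io import ScrRecording, SessionDesign
from .preprocess import FilterSpec, DEFAULT_HP, preprocess_pipeline
from .response_function import OdeRF, canonical_rf, estimate_individual_rf, NoPeakError
from .inversion import InversionOptions, SaEstimates, invert_session
from .benchmarks import peak_score_session, scores_to_frame
from .evaluation import (ComparisonResult, exclude_reinforced,
                         z_standardise, cell_means, predictive_validity)

__all__ = [
    "analyse_session_dcm",
    "analyse_session_peak",
    "choose_rf",
    "cohort_validity",
]

log = logging.getLogger(__name__)


def choose_rf(rec: ScrRecording, design: SessionDesign,
              rf_choice: str = "canonical") -> OdeRF:
    """Canonical RF, or an individual RF with canonical fallback when no
    peak can be identified in the participant's first principal component."""
    if rf_choice == "canonical":
        return canonical_rf()
    if rf_choice != "individual":
        raise ValueError(f"unknown rf_choice {rf_choice!r}")
    try:
        return estimate_individual_rf(rec, design)
    except NoPeakError as e:
        log.warning("individual RF estimation failed (%s); using canonical", e)
        return canonical_rf()


def analyse_session_dcm(rec: ScrRecording, design: SessionDesign,
                        opts: InversionOptions = InversionOptions(),
                        hp: FilterSpec = DEFAULT_HP, despike: bool = False,
                        preprocessed: bool = False) -> SaEstimates:
    """Model-based SA estimates for one session (preprocess + invert)."""
    pre = rec if preprocessed else preprocess_pipeline(rec, hp, despike=despike)
    rf = choose_rf(pre, design, opts.rf_choice)
    return invert_session(pre, design, rf, opts)


def analyse_session_peak(rec: ScrRecording, design: SessionDesign,
                         hp: FilterSpec = DEFAULT_HP, despike: bool = False,
                         preprocessed: bool = False) -> SaEstimates:
    """Trough-to-peak SA scores for one session, in the estimate layout."""
    pre = rec if preprocessed else preprocess_pipeline(rec, hp, despike=despike)
    scores, _ = peak_score_session(pre, design)
    pid = design.trials[0].participant_id if design.trials else ""
    return SaEstimates(scores_to_frame(scores, design), participant_id=pid,
                       meta={"method": "peak"})


def cohort_validity(estimates: list[SaEstimates],
                    designs: list[SessionDesign],
                    z: bool = False) -> ComparisonResult:
    """Group-level predictive validity for one set of per-participant
    estimates.

    z-standardisation (when requested) runs across all trials of a
    participant; reinforced CS+ trials are then excluded and cell means
    formed.
    """
    frames = []
    for i, (est, design) in enumerate(zip(estimates, designs)):
        if z:
            est = z_standardise(est)
        est = exclude_reinforced(est, design)
        pid = est.participant_id or f"sub-{i:02d}"
        frames.append(cell_means(est, participant=pid))
    return predictive_validity(pd.concat(frames, ignore_index=True))
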