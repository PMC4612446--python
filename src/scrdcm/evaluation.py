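"""Predictive-validity evaluation and model comparison.

A method's sympathetic arousal (SA) estimates are judged by how well they
discriminate CS+ from CS− at the group level.  Reinforced CS+ trials are
excluded (the unconditioned response would confound the comparison), cell
means per participant and CS type are formed, and CS type is regressed on
the SA cell means together with one constant per participant — algebraically
a paired t-test on the CS+/CS− difference.  Model evidence is summarised by
the negative log likelihood

    NLL = n * log(RSS / n)

and models are compared through log Bayes factors LBF = NLL − NLL_ref,
where lower LBF means higher predictive validity and |LBF| > 3 is decisive
(the probability of the null given the data at that bound is
1/exp(3) ≈ 0.0498 ≤ 0.05).

Because the dependent variable (CS type) is shared by all compared models,
rescaling the SA estimates has no effect on NLL or t: the scale is absorbed
by the regression coefficient and any shift by the participant constants.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SessionDesign, CS_PLUS, CS_MINUS
from .inversion import SaEstimates

__all__ = [
    "ComparisonResult",
    "DECISIVE_LBF",
    "exclude_reinforced",
    "z_standardise",
    "cell_means",
    "predictive_validity",
    "log_bayes_factor",
]

log = logging.getLogger(__name__)

#: |LBF| above this is conventionally decisive; null probability 1/exp(3)
DECISIVE_LBF = 3.0

#: numeric CS-type coding used as the regression label
CS_CODING = {CS_PLUS: 1.0, CS_MINUS: 0.0}


@dataclass(frozen=True)
class ComparisonResult:
    """Fit summary of the CS-type regression for one set of SA estimates."""

    nll: float    # n * log(rss / n), the negative model evidence
    rss: float
    n: int        # rows in the regression (2 per participant)
    t: float      # t-statistic of the SA coefficient (paired-t analogue)
    df: int       # n - (participants + 1)
    lbf: float | None = None  # nll - nll_reference, when a reference is set

    @property
    def decisive(self) -> bool:
        return self.lbf is not None and abs(self.lbf) > DECISIVE_LBF


def exclude_reinforced(estimates: SaEstimates,
                       design: SessionDesign) -> SaEstimates:
    """Drop reinforced CS+ trials from the estimate table.

    All CS− trials and non-reinforced CS+ trials are retained.
    """
    if len(estimates.df) != design.n_trials:
        raise ValueError("estimates not aligned with the session design")
    keep = ~design.reinforced
    out = estimates.copy()
    out.df = out.df.loc[keep].reset_index(drop=True)
    if not any(tr.cs_type == CS_PLUS and not tr.reinforced
               for tr in design.trials):
        log.warning("all CS+ trials reinforced; CS+ cell will be empty")
    return out


def z_standardise(estimates: SaEstimates) -> SaEstimates:
    """Centre and scale one participant's SA amplitudes to mean 0, SD 1.

    Removes between-subject amplitude variance (peripheral gain) before the
    group-level regression.  Uses the sample SD (n − 1).
    """
    amps = estimates.sa
    if amps.size < 2:
        raise ValueError("need >= 2 trials to z-standardise")
    sd = amps.std(ddof=1)
    if not sd > 1e-12 * max(1.0, float(np.abs(amps).max())):
        raise ValueError(
            f"participant {estimates.participant_id!r}: zero variance in SA "
            "estimates, cannot z-standardise")
    out = estimates.copy()
    out.df = out.df.assign(amplitude=(amps - amps.mean()) / sd)
    out.meta["z_standardised"] = True
    return out


def cell_means(estimates: SaEstimates, participant: str | None = None
               ) -> pd.DataFrame:
    """Mean SA per CS type for one participant (excluded trials are
    already absent from the table)."""
    pid = participant if participant is not None else estimates.participant_id
    g = estimates.df.groupby("cs_type")["amplitude"].mean()
    return pd.DataFrame({
        "participant": pid,
        "cs_type": g.index,
        "sa": g.to_numpy(float),
    })


def predictive_validity(cells: pd.DataFrame,
                        coding: dict | None = None) -> ComparisonResult:
    """Fit the CS-type regression on per-participant cell means.

    ``cells`` needs columns ``participant``, ``cs_type``, ``sa`` with one
    CS+ and one CS− row per participant.  The model is
    ``label ~ sa + one constant per participant`` (no global intercept),
    labels coded CS+ = 1, CS− = 0 by default.  The participant constants
    are absorbed by within-participant demeaning (Frisch–Waugh), which is
    algebraically the full dummy-variable least-squares fit and reduces to
    a paired t-test on the CS+/CS− differences; a degenerate predictor
    (no within-participant variation) yields coefficient 0 and t = 0.
    Participants with a missing cell are dropped with a warning; fewer
    than 3 complete participants is an error.
    """
    counts = cells.dropna(subset=["sa"]).groupby("participant")["cs_type"].nunique()
    complete = counts.index[counts == 2]
    dropped = sorted(set(cells["participant"]) - set(complete))
    if dropped:
        log.warning("dropping participants with a missing cell: %s", dropped)
    cells = cells[cells["participant"].isin(complete)]
    participants = sorted(set(cells["participant"]))
    n_p = len(participants)
    if n_p < 3:
        raise ValueError(f"need >= 3 complete participants, have {n_p}")
    n = len(cells)
    y = cells["cs_type"].map(coding or CS_CODING).to_numpy(float)
    sa = cells["sa"].to_numpy(float)
    pid = cells["participant"].to_numpy()
    # within-participant demeaning absorbs the participant constants
    y_t = y - pd.Series(y).groupby(pid).transform("mean").to_numpy()
    x_t = sa - pd.Series(sa).groupby(pid).transform("mean").to_numpy()
    sxx = float(x_t @ x_t)
    beta = float(x_t @ y_t) / sxx if sxx > 0 else 0.0
    resid = y_t - beta * x_t
    rss = float(resid @ resid)
    df = n - (n_p + 1)
    if sxx > 0 and rss > 0:
        t = beta / math.sqrt(rss / df / sxx)
    else:
        t = 0.0
    nll = n * math.log(rss / n) if rss > 0 else -math.inf
    return ComparisonResult(nll=nll, rss=rss, n=n, t=t, df=df)


def log_bayes_factor(result: ComparisonResult,
                     reference: ComparisonResult) -> float:
    """LBF = NLL − NLL_reference; negative favours the evaluated model."""
    if result.n != reference.n:
        raise ValueError(f"mismatched regressions: n={result.n} vs "
                         f"n={reference.n}")
    return result.nll - reference.nll
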