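"""Trial-wise MAP inversion of the forward model.

The session is split into overlapping chunks of ``trial_depth`` successive
trials (window step 1).  Each chunk maximises a penalised Gaussian
log-likelihood — squared residuals between predicted and observed trace
over the chunk window plus Gaussian prior penalties in transformed
parameter space — with a deterministic trust-region Gauss-Newton scheme
started from the prior means (the chunk noise variance is re-estimated
from the residuals between passes until it stabilises).  Parameter transforms enforce the model
constraints exactly: log for amplitudes and dispersions (non-negativity),
scaled logit for the anticipatory onset (confined to the CS-to-US window).
Estimates for a chunk's first trial are retained (the final chunk retains
all of its trials) and their predicted contribution, including response
tails, is carried forward so later chunks see the past.

Inside the optimiser the linear response is evaluated through a
precomputed burst-response table (the response-function kernel convolved
with unit Gaussians on a dispersion grid), which keeps each objective and
analytic-gradient evaluation cheap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .io import ScrRecording, SessionDesign
from .response_function import OdeRF, impulse_response

__all__ = [
    "Priors",
    "InversionOptions",
    "SaEstimates",
    "BurstResponseTable",
    "CarryState",
    "invert_chunk",
    "invert_session",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Priors:
    """Gaussian priors in transformed parameter space (normalised units)."""

    amp_log_mean: float = math.log(0.1)   # amplitude prior median 0.1
    amp_log_sd: float = 1.0
    onset_z_sd: float = 1.0               # logit-space onset, centred mid-window
    disp_log_mean: float = math.log(0.3)  # dispersion prior median 0.3 s
    disp_log_sd: float = 0.5
    sf_log_mean: float = math.log(0.02)   # SF amplitude prior median (small)
    sf_log_sd: float = 1.5
    scl_sd: float = 0.2                   # per-trial SCL increment
    noise_floor: float = 1e-8             # variance floor for the chunk noise


@dataclass(frozen=True)
class InversionOptions:
    trial_depth: int = 2
    include_scl: bool = True
    rf_choice: str = "canonical"          # "canonical" | "individual"
    priors: Priors = field(default_factory=Priors)
    max_iterations: int = 80
    tol: float = 1e-9                     # relative objective-change tolerance
    seed: int = 0                         # kept for interface symmetry; unused
    sf_grid: float | None = 2.0           # SF candidate spacing (s); None = no SF
    sf_dispersion: float = 0.3            # fixed SF burst width (s)
    kernel_duration: float = 60.0         # response tail length carried (s)

    def __post_init__(self) -> None:
        if self.trial_depth < 1:
            raise ValueError("trial_depth must be >= 1")
        if not self.tol > 0:
            raise ValueError("tolerance must be > 0")


class BurstResponseTable:
    """Response of the RF to unit-peak Gaussian bursts, tabulated.

    ``K(tau; d)`` is the RF kernel convolved with a unit-peak Gaussian of
    SD ``d`` (support truncated at +-6 d), sampled on a fine lag grid and a
    geometric dispersion grid.  Lookups interpolate linearly in lag and in
    dispersion; lag and dispersion derivatives are the exact derivatives of
    the interpolant, so optimiser gradients are consistent.
    """

    def __init__(self, rf: OdeRF, rate: float, d_min: float = 0.05,
                 d_max: float = 2.0, n_d: int = 81, duration: float = 60.0,
                 oversample: int = 8):
        self.rf = rf
        self.rate = rate
        self.dt = 1.0 / (oversample * rate)
        self.d_grid = np.geomspace(d_min, d_max, n_d)
        tau0 = -6.0 * d_max
        self.tau = np.arange(tau0, duration, self.dt)
        h = impulse_response(rf, duration, 1.0 / self.dt).values
        U = np.exp(-0.5 * (self.tau[None, :] / self.d_grid[:, None]) ** 2)
        U[np.abs(self.tau[None, :]) > 6.0 * self.d_grid[:, None]] = 0.0
        from scipy.signal import fftconvolve
        self.K = fftconvolve(U, h[None, :], axes=1)[:, :self.tau.size] * self.dt

    _cache: dict = {}

    @classmethod
    def cached(cls, rf: OdeRF, rate: float, **kw) -> "BurstResponseTable":
        """Shared table instance; the kernel depends only on the RF
        coefficients and rates, so repeated sessions reuse it."""
        key = (round(rf.a1, 12), round(rf.a2, 12), round(rf.a3, 12),
               round(rf.b, 12), rate, tuple(sorted(kw.items())))
        if key not in cls._cache:
            if len(cls._cache) > 8:  # keep the cache tiny
                cls._cache.clear()
            cls._cache[key] = cls(rf, rate, **kw)
        return cls._cache[key]

    def _d_weights(self, d: float) -> tuple[int, float]:
        d = float(np.clip(d, self.d_grid[0], self.d_grid[-1]))
        i = int(np.clip(np.searchsorted(self.d_grid, d) - 1, 0,
                        self.d_grid.size - 2))
        w = (d - self.d_grid[i]) / (self.d_grid[i + 1] - self.d_grid[i])
        return i, w

    def _segment(self, K: np.ndarray, jc: np.ndarray, frac: np.ndarray,
                 valid: np.ndarray):
        a, b = K[jc], K[jc + 1]
        val = np.where(valid, a + frac * (b - a), 0.0)
        slope = np.where(valid, (b - a) / self.dt, 0.0)
        return val, slope

    def response(self, lags: np.ndarray, d: float,
                 with_derivs: bool = False):
        """K (and optionally dK/dlag, dK/dd) at the given lags.

        Derivatives are the exact derivatives of the bilinear interpolant,
        so the optimiser's analytic gradients match the objective exactly.
        """
        i, w = self._d_weights(d)
        pos = (np.asarray(lags) - self.tau[0]) / self.dt
        j = np.floor(pos).astype(np.int64)
        valid = (j >= 0) & (j < self.tau.size - 1)
        jc = np.clip(j, 0, self.tau.size - 2)
        frac = pos - j
        k = (1.0 - w) * self.K[i] + w * self.K[i + 1]
        val, dval_dlag = self._segment(k, jc, frac, valid)
        if not with_derivs:
            return val
        kd = (self.K[i + 1] - self.K[i]) / (self.d_grid[i + 1] - self.d_grid[i])
        dval_dd, _ = self._segment(kd, jc, frac, valid)
        return val, dval_dlag, dval_dd


@dataclass
class CarryState:
    """What one chunk hands to the next.

    ``trace`` holds the predicted contribution of all finalised trials
    (burst response tails and SCL ramps) over the whole recording — the
    role of the carried ODE state.  ``baseline`` is the tonic level fitted
    in the first chunk.
    """

    trace: np.ndarray
    baseline: float | None = None


@dataclass
class ChunkResult:
    trial_params: list            # forward_model.TrialParams per chunk trial
    sf_onsets: list[np.ndarray]
    sf_amplitudes: list[np.ndarray]
    objective: float              # negative penalised misfit at the optimum
    converged: bool
    n_iter: int
    trajectory: np.ndarray        # objective value per accepted iteration
    baseline: float


def _sigmoid(z: np.ndarray | float):
    return 1.0 / (1.0 + np.exp(-z))


class _ChunkModel:
    """Packs chunk parameters, evaluates prediction, objective and gradient."""

    def __init__(self, obs: np.ndarray, t_w: np.ndarray, trials: list,
                 design: SessionDesign, table: BurstResponseTable,
                 opts: InversionOptions, carry_w: np.ndarray,
                 baseline_fixed: float | None, end_time: float):
        self.obs = obs
        self.t_w = t_w
        self.trials = trials          # (global_index, TrialEvent)
        self.design = design
        self.table = table
        self.opts = opts
        self.carry_w = carry_w
        self.baseline_fixed = baseline_fixed
        p = opts.priors

        # parameter layout: per trial [amp, onset, disp, evoked(, scl)],
        # then SF amplitudes per trial, then baseline if free
        self.sf_onsets = []
        means, sds, names = [], [], []
        for j, (gi, tr) in enumerate(trials):
            means += [p.amp_log_mean, 0.0, p.disp_log_mean, p.amp_log_mean]
            sds += [p.amp_log_sd, p.onset_z_sd, p.disp_log_sd, p.amp_log_sd]
            names += [f"amp{j}", f"onset{j}", f"disp{j}", f"evoked{j}"]
            if opts.include_scl:
                means.append(0.0)
                sds.append(p.scl_sd)
                names.append(f"scl{j}")
            nxt = design.next_onset(gi, default=end_time)
            if opts.sf_grid:
                grid = np.arange(tr.cs_onset + design.cs_duration + 1.0,
                                 nxt - 0.5, opts.sf_grid)
            else:
                grid = np.empty(0)
            self.sf_onsets.append(grid)
        for j, grid in enumerate(self.sf_onsets):
            means += [p.sf_log_mean] * grid.size
            sds += [p.sf_log_sd] * grid.size
            names += [f"sf{j}_{s}" for s in range(grid.size)]
        self.free_baseline = baseline_fixed is None
        if self.free_baseline:
            # flat prior; initialise at the window mean so the optimisation
            # is exactly equivariant under constant shifts of the recording
            means.append(float(obs.mean()))
            sds.append(np.inf)
            names.append("baseline")
        self.mu = np.array(means)
        self.sd = np.array(sds)
        self.names = names
        self.n_params = self.mu.size
        # box constraints for numerical hygiene (transform ranges stay sane)
        lo = np.full(self.n_params, -np.inf)
        hi = np.full(self.n_params, np.inf)
        for i, nm in enumerate(names):
            if nm.startswith(("amp", "evoked", "sf")):
                lo[i], hi[i] = -12.0, 6.0
            elif nm.startswith("onset"):
                lo[i], hi[i] = -7.0, 7.0
            elif nm.startswith("disp"):
                lo[i], hi[i] = math.log(table.d_grid[0]), math.log(table.d_grid[-1])
        self.bounds = list(zip(lo, hi))

        self._build_fixed_columns()

    def _build_fixed_columns(self) -> None:
        """Precompute regressor columns whose shape never changes during
        optimisation: evoked responses (fixed onset and width), SF candidate
        responses (fixed grid and width), SCL ramps and the baseline.  Only
        the anticipatory bursts need re-evaluation inside the optimiser."""
        opts, design, table, t_w = self.opts, self.design, self.table, self.t_w
        stride = 5 if opts.include_scl else 4
        cols, col_idx, col_is_amp = [], [], []
        self.ant = []  # (param offset, cs_onset) per chunk trial
        k = 0
        for j, (gi, tr) in enumerate(self.trials):
            self.ant.append((k, tr.cs_onset))
            cols.append(table.response(t_w - (tr.cs_onset + design.soa),
                                       design.evoked_dispersion))
            col_idx.append(k + 3)
            col_is_amp.append(True)
            if opts.include_scl:
                cols.append(self._ramp(gi, tr))
                col_idx.append(k + 4)
                col_is_amp.append(False)
            k += stride
        for grid in self.sf_onsets:
            for o in grid:
                cols.append(table.response(t_w - o, opts.sf_dispersion))
                col_idx.append(k)
                col_is_amp.append(True)
                k += 1
        if self.free_baseline:
            cols.append(np.ones_like(t_w))
            col_idx.append(k)
            col_is_amp.append(False)
        self.Phi = np.column_stack(cols)
        self.col_idx = np.asarray(col_idx)
        self.col_is_amp = np.asarray(col_is_amp)

    # -- prediction ------------------------------------------------------
    def predict(self, theta: np.ndarray, parts: bool = False):
        """Predicted trace over the window; with ``parts`` also the
        gradient of the prediction w.r.t. every free parameter."""
        design, table = self.design, self.table
        t_w = self.t_w
        th_cols = theta[self.col_idx]
        coef = np.where(self.col_is_amp, np.exp(th_cols), th_cols)
        pred = self.carry_w + self.Phi @ coef
        if not self.free_baseline:
            pred = pred + self.baseline_fixed
        grads = {} if parts else None
        if parts:
            for c, (p, is_amp) in enumerate(zip(self.col_idx, self.col_is_amp)):
                grads[p] = self.Phi[:, c] * coef[c] if is_amp else self.Phi[:, c]
        for k, cs_onset in self.ant:
            a = math.exp(theta[k])
            s = _sigmoid(theta[k + 1])
            onset = cs_onset + design.soa * s
            d = math.exp(theta[k + 2])
            if parts:
                val, dlag, dd = table.response(t_w - onset, d, with_derivs=True)
                grads[k] = a * val
                grads[k + 1] = -a * dlag * design.soa * s * (1.0 - s)
                grads[k + 2] = a * dd * d
            else:
                val = table.response(t_w - onset, d)
            pred = pred + a * val
        return (pred, grads) if parts else pred

    def _ramp(self, gi: int, tr) -> np.ndarray:
        nxt = self.design.next_onset(gi, default=tr.cs_onset + 10.0)
        return np.clip((self.t_w - tr.cs_onset) / (nxt - tr.cs_onset), 0.0, 1.0)

    # -- objective -------------------------------------------------------
    def set_noise(self, theta0: np.ndarray) -> float:
        r0 = self.obs - self.predict(theta0)
        self.sigma2 = max(float(np.var(r0)), self.opts.priors.noise_floor)
        return self.sigma2

    def _prior_z(self, theta: np.ndarray) -> np.ndarray:
        dz = (theta - self.mu) / self.sd
        dz[~np.isfinite(self.sd)] = 0.0
        return dz

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        """Stacked weighted residuals: data misfit then prior penalties.

        Half their squared norm is the penalised objective."""
        r = (self.predict(theta) - self.obs) / math.sqrt(self.sigma2)
        return np.concatenate([r, self._prior_z(theta)])

    def jacobian(self, theta: np.ndarray) -> np.ndarray:
        pred, grads = self.predict(theta, parts=True)
        n_w = self.obs.size
        J = np.zeros((n_w + self.n_params, self.n_params))
        sig = math.sqrt(self.sigma2)
        for i in range(self.n_params):
            J[:n_w, i] = grads[i] / sig
        for i, s in enumerate(self.sd):
            if np.isfinite(s):
                J[n_w + i, i] = 1.0 / s
        return J

    def objective(self, theta: np.ndarray):
        """Penalised objective and its gradient (for diagnostics/tests)."""
        res = self.residuals(theta)
        J = self.jacobian(theta)
        return 0.5 * float(res @ res), J.T @ res


@dataclass
class SaEstimates:
    """Per-trial sympathetic arousal estimates for one session.

    ``df`` has one row per trial: anticipatory amplitude / onset / duration,
    evoked amplitude, the chunk objective (negative penalised misfit, a
    free-energy-style diagnostic) and a convergence flag.
    """

    df: pd.DataFrame
    participant_id: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def sa(self) -> np.ndarray:
        """The SA estimate used downstream: the anticipatory amplitude."""
        return self.df["amplitude"].to_numpy(float)

    def copy(self) -> "SaEstimates":
        return SaEstimates(self.df.copy(), self.participant_id, dict(self.meta))


def invert_chunk(rec: ScrRecording, design: SessionDesign, first_trial: int,
                 rf: OdeRF, opts: InversionOptions,
                 carry_in: CarryState | None = None,
                 table: BurstResponseTable | None = None,
                 depth: int | None = None) -> ChunkResult:
    """MAP-invert one chunk of ``depth`` trials starting at ``first_trial``.

    Returns the chunk posterior mode: trial parameters for trials
    ``first_trial .. first_trial + depth - 1`` plus the objective value.
    Non-convergence within ``max_iterations`` is flagged and the best
    iterate returned.
    """
    from .forward_model import BurstParams, TrialParams

    depth = opts.trial_depth if depth is None else depth
    n = design.n_trials
    if first_trial < 0 or first_trial + depth > n:
        raise ValueError("chunk extends beyond the session")
    if carry_in is None:
        carry_in = CarryState(np.zeros(rec.n), baseline=None)
    if table is None:
        table = BurstResponseTable.cached(rf, rec.rate, duration=opts.kernel_duration)

    end_time = rec.t0 + rec.n / rec.rate
    t_start = design.trials[first_trial].cs_onset
    if first_trial + depth < n:
        t_stop = design.trials[first_trial + depth].cs_onset
    else:
        t_stop = end_time
    i0 = int(round((t_start - rec.t0) * rec.rate))
    i1 = min(int(round((t_stop - rec.t0) * rec.rate)), rec.n)
    if i1 - i0 < 4:
        raise ValueError("chunk window lies outside the recording")
    t_w = rec.t0 + np.arange(i0, i1) / rec.rate
    obs = rec.values[i0:i1]
    trials = [(first_trial + j, design.trials[first_trial + j])
              for j in range(depth)]
    model = _ChunkModel(obs, t_w, trials, design, table, opts,
                        carry_w=carry_in.trace[i0:i1],
                        baseline_fixed=carry_in.baseline, end_time=end_time)
    lo = np.array([b[0] for b in model.bounds])
    hi = np.array([b[1] for b in model.bounds])
    theta = model.mu.copy()
    # iterated trust-region Gauss-Newton: the chunk noise variance starts
    # from the residual at the prior means (a deliberate overestimate while
    # the signal is unexplained) and is re-estimated from the residuals of
    # each pass until it stabilises, so the likelihood ends up carrying its
    # proper weight even for near-noiseless data
    prev_sigma2 = np.inf
    for _ in range(8):
        model.set_noise(theta)
        if model.sigma2 > 0.7 * prev_sigma2:
            break
        prev_sigma2 = model.sigma2
        history = []

        def jac_logged(th):
            # the solver evaluates the Jacobian at accepted iterates only,
            # so this doubles as the objective trajectory
            history.append(0.5 * float(np.sum(model.residuals(th) ** 2)))
            return model.jacobian(th)

        res = optimize.least_squares(
            model.residuals, theta, jac=jac_logged, bounds=(lo, hi),
            method="trf", x_scale="jac", ftol=opts.tol, xtol=1e-12,
            gtol=1e-10, max_nfev=opts.max_iterations)
        theta = res.x
    converged = res.status > 0 and res.nfev < opts.max_iterations
    if not converged:
        log.warning("chunk at trial %d: no convergence in %d iterations",
                    first_trial, opts.max_iterations)

    stride = 5 if opts.include_scl else 4
    params, sf_amps = [], []
    k = 0
    for j, (gi, tr) in enumerate(trials):
        th = theta[k:k + stride]
        onset = tr.cs_onset + design.soa * _sigmoid(th[1])
        params.append(TrialParams(
            anticipatory=BurstParams(math.exp(th[0]), onset, math.exp(th[2])),
            evoked_amplitude=math.exp(th[3]),
            scl_change=(th[4] if opts.include_scl else 0.0),
        ))
        k += stride
    for grid in model.sf_onsets:
        sf_amps.append(np.exp(theta[k:k + grid.size]))
        k += grid.size
    baseline = theta[-1] if model.free_baseline else carry_in.baseline
    return ChunkResult(params, model.sf_onsets, sf_amps,
                       objective=-float(res.cost), converged=converged,
                       n_iter=int(res.nfev),
                       trajectory=-np.asarray(history, dtype=float),
                       baseline=float(baseline))


def invert_session(rec: ScrRecording, design: SessionDesign, rf: OdeRF,
                   opts: InversionOptions = InversionOptions()) -> SaEstimates:
    """Slide a window of ``trial_depth`` trials (step 1) over the session.

    Each chunk's first-trial estimates are retained (the final window
    retains all its trials); finalised trials' response tails and SCL
    ramps are carried forward into later chunks.
    """
    n = design.n_trials
    end_time = rec.t0 + rec.n / rec.rate
    if end_time < design.onsets[-1] + design.cs_duration:
        raise ValueError("recording shorter than the session design span")
    depth = opts.trial_depth
    if depth > n:
        log.warning("trial depth %d clamped to %d (session has %d trials)",
                    depth, n, n)
        depth = n
    table = BurstResponseTable.cached(rf, rec.rate, duration=opts.kernel_duration)
    carry = CarryState(np.zeros(rec.n), baseline=None)

    rows = []
    for k in range(n - depth + 1):
        chunk = invert_chunk(rec, design, k, rf, opts, carry_in=carry,
                             table=table, depth=depth)
        if carry.baseline is None:
            carry.baseline = chunk.baseline
        retained = range(depth) if k == n - depth else range(1)
        for j in retained:
            gi = k + j
            tp = chunk.trial_params[j]
            _finalise(carry, rec, design, gi, tp, chunk.sf_onsets[j],
                      chunk.sf_amplitudes[j], table, opts)
            tr = design.trials[gi]
            rows.append({
                "trial": gi, "cs_type": tr.cs_type,
                "reinforced": int(tr.reinforced), "cs_onset": tr.cs_onset,
                "amplitude": tp.anticipatory.amplitude,
                "onset": tp.anticipatory.onset,
                "duration": tp.anticipatory.dispersion,
                "evoked_amplitude": tp.evoked_amplitude,
                "objective": chunk.objective,
                "converged": int(chunk.converged),
            })
    df = pd.DataFrame(rows)
    pid = design.trials[0].participant_id if design.trials else ""
    return SaEstimates(df, participant_id=pid,
                       meta={"rf": rf.label, "trial_depth": depth,
                             "include_scl": opts.include_scl,
                             "baseline": carry.baseline})


def _finalise(carry: CarryState, rec: ScrRecording, design: SessionDesign,
              gi: int, tp, sf_onsets: np.ndarray, sf_amps: np.ndarray,
              table: BurstResponseTable, opts: InversionOptions) -> None:
    """Add a finalised trial's predicted contribution to the carry trace."""
    t = rec.t0 + np.arange(rec.n) / rec.rate
    tr = design.trials[gi]

    def add(amp, onset, d):
        if amp <= 0:
            return
        i0 = max(0, int((onset - 6 * d - rec.t0) * rec.rate))
        i1 = min(rec.n, int((onset + opts.kernel_duration - rec.t0) * rec.rate))
        carry.trace[i0:i1] += amp * table.response(t[i0:i1] - onset, d)

    add(tp.anticipatory.amplitude, tp.anticipatory.onset,
        tp.anticipatory.dispersion)
    add(tp.evoked_amplitude, tr.cs_onset + design.soa,
        design.evoked_dispersion)
    for o, a in zip(sf_onsets, sf_amps):
        add(a, o, opts.sf_dispersion)
    if opts.include_scl and tp.scl_change != 0.0:
        nxt = design.next_onset(gi, default=tr.cs_onset + 10.0)
        i0 = max(0, int((tr.cs_onset - rec.t0) * rec.rate))
        ramp = np.clip((t[i0:] - tr.cs_onset) / (nxt - tr.cs_onset), 0.0, 1.0)
        carry.trace[i0:] += tp.scl_change * ramp
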