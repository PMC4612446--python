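# Methods

## The model

Skin conductance responses (SCR) are treated as the output of a causal
chain: a central state of sympathetic arousal (SA) drives bursts of
sudomotor nerve activity, and each burst is transformed into an observable
conductance change by a peripheral response function (RF).  In a delay
fear-conditioning trial the model places

* **one anticipatory burst** per trial, with free amplitude, onset and
  duration.  The onset is constrained to the window between CS onset and
  the potential US, i.e. `[cs_onset, cs_onset + soa]` with `soa = 3.5 s`;
  the burst is a Gaussian in time with the amplitude parameterised as peak
  height (arbitrary units after normalisation) and the duration as the
  Gaussian SD (s);
* **one US-evoked burst** per trial at `cs_onset + soa`, with free
  amplitude and fixed width (0.3 s — a sub-second burst for a punctate
  stimulus).  The model is deliberately not told whether the US was
  actually delivered;
* **spontaneous-fluctuation (SF) bursts** confined to each inter-trial
  interval.  Candidate SFs sit on a 2 s grid with fixed 0.3 s width and
  free amplitudes; a dense grid with free amplitudes approximates freely
  timed SFs while keeping the problem smooth;
* **a tonic skin conductance level (SCL)**: a constant baseline plus,
  optionally, a piecewise-linear drift with one node per trial onset
  (free signed increment per trial), smoothed by a first-order lag with a
  30 s time constant so the drift stays spectrally disjoint from phasic
  responses.  When SCL modelling is off, the baseline is estimated on the
  first trial and held constant.

The summed burst input `u(t)` drives a third-order linear ODE

    x''' + a1 x'' + a2 x' + a3 x = b u(t),

whose impulse response is the SCR shape.  The canonical RF shipped with
the package is a least-squares fit of this ODE to a smoothed bi-exponential
canonical SCR shape (rise time constant 1 s, decay 4 s, Gaussian smoothing
SD 1.5 s, time constants bounded to [0.7, 8] s during the fit).  The frozen
coefficients — `a = (3.088582, 2.702070, 0.472324)`, `b = 3.195605`,
normalised so the impulse response has unit peak at 2.47 s latency — live
in `src/scrdcm/data/canonical_rf.json`; all downstream numbers are
reproducible from that file.  An individual RF can instead be estimated
per participant (below).

### Numerical integration

`predict_scr` integrates the ODE with a fixed-step classical 4th-order
scheme at 10x the output rate, with the input evaluated on the half-step
grid.  Because the system is linear and time-invariant the update is an
exact linear recurrence in the state, which is evaluated as three
`lfilter` passes (one per input tap) and then decimated — bit-identical
to the step-by-step loop but vectorised.  Against an independent
convolution oracle (analytic impulse response at 1000 Hz) the relative
error is ~1e-9.  Gaussian bursts are truncated at ±6 SD (relative area
loss 2e-9); the predicted trace is exactly zero before the input support
begins.  Note that a Gaussian burst is not strictly causal at tighter
margins: the response magnitude just before `onset − 3·SD` scales with
amplitude × SD (≈ 5e-6 for a unit burst of 0.3 s width) because of the
input's own tail mass — an intrinsic property of the burst shape, not an
integrator artefact.

## Preprocessing

Applied in order: optional median despike (centred 11-sample window,
truncated at the edges; intended for 2 ms MRI gradient spikes at 1000 Hz)
→ first-order Butterworth low-pass at 5 Hz (single forward pass) →
downsampling to 10 Hz (integer decimation, else linear interpolation) →
first-order Butterworth high-pass applied twice (forward+backward =
"bi-directional", zero net phase; forward twice = "uni-directional") →
normalisation (subtract minimum, divide by sample SD, n−1 denominator).

Both high-pass directions share the squared first-order magnitude
response (amplitude exactly 1/2 at the cutoff); they differ only in
phase.  A first-order high-pass has phase lead, so uni-directional
filtering moves SCR peaks to *earlier* samples (≈ 6 samples at 10 Hz for
the default 0.0159 Hz cutoff), while bi-directional filtering preserves
peak latency exactly — the mechanism behind the bi-directional default.
Filter state is initialised at the step steady state and both ends are
padded by odd reflection over three filter time constants, which
suppresses startup transients to below 1e-6.  The six high-pass cutoffs
{0.005, 0.01, 0.0159, 0.035, 0.05, 0.06} Hz are configuration presets;
0.0159 Hz (10 s time constant) is the default.

The despike edge rule (truncated windows) makes the filter an identity on
smooth data only away from the first/last half-window; on a sloping trace
the edge median is biased by slope × half-window.

## Individual response function

Per trial the segment from `cs_onset + soa` (the last possible evoked
response) to the next trial onset is extracted; segments are truncated to
the shortest window and variance-normalised so single large trials cannot
dominate.  The first principal component is the first right singular
vector of the uncentred trials × samples matrix (uncentred, so the
event-locked mean shape is retained), with its sign chosen to make the
peak positive.  A peak is "identifiable" when an interior local maximum
exceeds the component median by 3x the robust point-noise SD (median
absolute successive difference / (0.6745·√2)); this separates smooth
event-locked components from noise-dominated or monotone ones, which
raise `NoPeakError` and trigger the canonical fallback.  The ODE is then
fitted to the peak-normalised component by least squares on the impulse
response with free gain, latency shift and offset, parameterised by three
log time constants — stability is guaranteed by construction.  The fitted
gain is normalised to unit peak; overall gain is absorbed by the amplitude
estimates downstream.

## Inversion

Estimation is maximum a posteriori in transformed parameter space:
log-amplitudes and log-dispersions (non-negativity), a scaled logit for
the anticipatory onset (hard window constraint), identity for SCL
increments.  Priors are Gaussian in transformed space:

| parameter | transform | prior | default |
|---|---|---|---|
| anticipatory / evoked amplitude | log | N(log 0.1, 1²) | median 0.1 n.u. |
| anticipatory onset | scaled logit | N(0, 1²) | mid-window |
| anticipatory duration | log | N(log 0.3, 0.5²) | median 0.3 s |
| SF amplitude | log | N(log 0.02, 1.5²) | median 0.02 n.u. |
| SCL increment | identity | N(0, 0.2²) | 0 |

(n.u. = normalised units.)  The SF prior median is deliberately smaller
than the response-burst prior: SF candidates are nuisance parameters, and
a log-normal prior cannot produce exact zeros, so a large median would
leave spurious pedestals in weakly identified directions that contaminate
the carried prediction.

The session is split into overlapping chunks of `trial_depth` successive
trials (default 2; 3 supported), window step 1, each chunk spanning from
its first CS onset to the onset of the trial after the chunk (or the
recording end).  Each chunk minimises squared residuals / (2σ²) plus the
prior penalties with a deterministic trust-region Gauss-Newton scheme
(`scipy.optimize.least_squares`, analytic Jacobian) started from the
prior means — no restarts, so results are exactly reproducible.  The
chunk noise variance σ² starts from the residual variance at the prior
means and is re-estimated from the residuals of each pass until it
stabilises (at most 8 passes, floor 1e-8 in normalised units); this lets
near-noiseless data sharpen the likelihood enough to pin the weakly
identified burst width, which would otherwise trade off against amplitude
under the priors.  Inside the optimiser, burst responses come from a
precomputed table of the RF kernel convolved with unit Gaussians on an
81-point geometric dispersion grid (lag step 1/80 s); lookups are linear
interpolants whose exact derivatives feed the Jacobian.  Table accuracy
against direct convolution is ~0.1%.

Each chunk's first-trial estimates are retained (the final chunk retains
all its trials); the retained trial's burst responses (60 s tails) and
SCL ramp are added to a carried prediction trace so later chunks account
for the past, and the tonic baseline fitted in the first chunk (free
intercept, initialised at the window mean — which makes the whole
procedure exactly equivariant under constant offsets of the recording) is
held fixed thereafter.  "Retain the first trial of each window" is the
conventional resolution of the duplicate estimates that overlapping
windows produce.

The SA estimate consumed by all downstream analyses is the anticipatory
burst amplitude.

## Peak-scoring benchmark

The response onset is the first sample in `[cs_onset+1, cs_onset+4.5]`
where the first derivative turns positive and stays positive for ≥ 0.3 s
(the trough serves as baseline; the window rule caps the peak search at
onset + 5 s, so peaks may fall up to ~9.5 s after CS onset).  The peak is
the maximum in `[onset+0.5, onset+5]`; the amplitude is the
baseline-corrected peak height, zero when no onset qualifies.  Per-type
participant means exclude reinforced CS+ trials.  No minimum-amplitude
criterion is applied.

## Evaluation

Reinforced CS+ trials are excluded (the unconditioned response would
confound the anticipatory comparison).  Optional within-participant
z-standardisation (mean 0, SD 1 across all of a participant's trials,
applied before the exclusion) removes between-subject amplitude variance.
Per participant and CS type, cell means of the SA estimates are formed
and CS type (coded CS+ = 1, CS− = 0) is regressed on the SA cell means
plus one constant per participant.  The fit is computed by
within-participant demeaning (Frisch–Waugh), which is algebraically the
full dummy-variable least-squares fit and identically the paired t-test
on the CS+/CS− differences (df = participants − 1); a degenerate
predictor yields t = 0.  Model evidence is `NLL = n·log(RSS/n)`; methods
are compared by `LBF = NLL − NLL_ref`, lower = better, |LBF| > 3 decisive
(null probability 1/e³ ≈ 0.0498).  Because the dependent variable is
shared, rescaling the SA estimates changes neither NLL nor t (scale goes
into the coefficient, shifts into the participant constants), and any
affine recoding of the labels adds a constant to NLL that cancels in
every LBF between models sharing labels.

## Synthetic cohorts

`CohortSpec` defaults encode a 90-trials-per-type delay-conditioning
design: 4 s CS, US or omission at 3.5 s, ITIs drawn from {7, 8, 9, 10,
11} s, 50% CS+ of which exactly half are reinforced, pseudo-randomised
order.  Ground-truth anticipatory amplitudes are truncated normals around
per-type means (CS+ 1.0, CS− 0.3, SD 0.3), onsets are truncated normals
centred mid-window with 0.8 s jitter SD — the lever that defeats
fixed-latency scorers — and durations truncated normals around 0.3 s.
Reinforced trials get an evoked burst (mean 1.0, SD 0.3).  SFs arrive at
4/min with exponential amplitudes (scale 0.15); the SCL drifts by
N(0, 0.05²) µS per trial on a 2 µS baseline; measurement noise is white
with SD 0.0744 µS = 10% of the peak response to a unit anticipatory
burst; and each participant carries a log-normal gain (SD 0.5)
multiplying all burst amplitudes and drift increments, which is what
makes z-standardisation worth having.  Recordings are synthesised at
100 Hz by default.  All draws come from
`SeedSequence([seed, participant])` sub-streams; a separate optional
`design_seed` freezes the trial skeleton across specs.

What the generator does **not** emulate: electrode drift and detachment
artefacts, motion, respiration coupling, non-linear amplitude saturation,
pore-diffusion dynamics, habituation/extinction trends across trials, or
MRI gradient artefacts beyond optional 2 ms test spikes.  Passing the
recovery and ordering tests therefore shows the estimator works when the
generative assumptions hold approximately; it does not certify behaviour
under artefacts the model excludes.

## Evaluation problem sizes

The standard evaluation setting used by the test suite and
`scripts/acceptance.py` is 20 participants × 40 trials per session
(20 per CS type) — the desk-scale version of the 90-per-type designs —
with 10 replicate cohorts in the test suite and 6 in the acceptance
script, and 20 single-participant sessions for the noisy
parameter-recovery correlation.  Under these conditions the package's
own runs give: noiseless amplitude recovery within ~2.5% on trials with
a measurable response (onsets within ~0.03 s), truth-versus-estimate
amplitude correlation ≈ 0.8 at 10% noise, a consistent z-standardisation
benefit, and a model-versus-peak-scoring LBF that is negative on average
(mean ≈ −4) and in 7 of 10 replicate cohorts.

A caveat on that last comparison: these synthetic conditions are much
cleaner than real recordings (both methods reach group-level t ≈ 13–32,
an order of magnitude above what conditioning data yield), and at that
ceiling the trough-to-peak scorer profits from its own zero-floor —
trials without a qualifying onset score exactly 0, which compresses the
CS− cell-mean variance so strongly that the scorer can out-discriminate
even the ground-truth amplitudes, while correlating *worse* with them
trial by trial (r ≈ 0.78 vs ≈ 0.87 for the model-based estimates).  The
model-based advantage on real data rests on lower-SNR, artefact- and
SF-contaminated recordings in which that floor misfires; simulated
cohorts of this cleanliness reproduce the direction of the comparison on
average but not on every replicate.

## Known limitations

* Anticipatory/evoked bursts that overlap in time are separated only by
  their width difference and the priors: because the model is not told
  whether a US occurred, every trial carries an evoked regressor at the
  US time, and an anticipatory burst whose onset lies within ~1 s of it
  is nearly collinear with that regressor under the ~1.5 s-wide kernel —
  the data determine the summed amplitude but not the split.  Recovery
  metrics therefore assess trials with onset ≥ 1 s from the US and a
  measurable amplitude.
* The inversion fits the unfiltered forward model to high-pass-filtered
  data, as the original procedure does; at the default 0.0159 Hz cutoff
  the distortion of phasic responses is small but not zero.
* Chunk windows truncate the response tails of the chunk's last trial;
  the sliding-window scheme re-estimates those trials with fuller context
  before retaining them, but the final session trial keeps its
  edge-window estimate.
* The MAP point estimates carry no posterior uncertainty; the objective
  value per chunk is a penalised-misfit diagnostic, not a marginal
  likelihood.
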