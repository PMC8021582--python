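# Methods

## Problem and model

Seizure detection is cast as anomaly detection in sequences: a
patient-specific forecaster learns, self-supervised, to predict the next
values of a channel from its recent past; epochs the model cannot predict —
ictal discharges in SEEG, irregular motion in video — surface as bursts of
prediction error. The approach assumes only that (i) most of the recording
is "normal" in the sense the model can learn, and (ii) anomalous epochs are
materially less predictable than background. No labels, artifact rejection,
or error-distribution assumptions are used.

### Preprocessing

SEEG channels are low-pass filtered with a one-pass, zero-phase, non-causal
FIR filter (windowed-sinc, Hamming window) and scaled affinely to [-1, 1].
Filter order comes from the Hamming window's ~3.3/N transition rule with a
default 12.5 Hz transition band at the 50 Hz cutoff; the symmetric kernel is
applied once with the group delay compensated by centering, and edges use
reflection padding. Scaling parameters are fit on the training segment only
and reapplied to the test segment (no leakage); values outside the fitted
range are not clipped. A constant segment maps to all zeros. Splits are
chronological and contiguous (train precedes test), default fraction 0.30
within the customary 20:80-50:50 band.

### Forecasting

Two interchangeable forecasters satisfy one contract — for every position
`t ≥ l_b`, predict the next `l_f` values from the preceding `l_b` observed
values, retaining the first predicted value per step so the error series
aligns one-to-one with `test[l_b:]`:

* **LSTM** (numpy): one recurrent layer, 80 hidden units by default, dense
  head, MSE loss, Adam (lr 3e-3), dropout 0.3 on the head input, forget-gate
  bias initialized to 1. Training runs at most 35 epochs with a
  chronological 20% validation split; early stopping fires after 5
  consecutive epochs that fail to reduce the validation MSE by at least
  0.003 *relative to the previous epoch* (the rule's literal reading, which
  the hand-stepped unit tests pin), and the best-validation weights are
  restored at the end. The backward pass is hand-derived and verified
  against finite differences in the test suite.
* **AR(p) baseline** (default p = 16): ordinary least squares with
  intercept; deterministic, trains in milliseconds, and satisfies the same
  rolling contract. Benchmarks use it for SEEG so ten-seed sweeps run in
  minutes.

The choice matters for the video path: least-squares AR learns *persistence*
whenever a level drop lands in its training segment, and persistence tracks
any test-time drop, erasing the error signal. The LSTM trained on mostly
regular data does not generalize to dips — every drop surfaces as error —
which is the behavior the video modality needs (catch everything, tolerate
false alarms). Video benchmarks therefore always use the LSTM.

Errors: `e(t) = |actual − predicted|`, smoothed by the standard EWMA
recursion with `α = 2/(span+1)`; default span is 1% of the error-series
length. Reconstruction quality is summarized as MAPE over samples with
`|actual| ≥ 10⁻³` (the signal crosses zero after scaling, so a denominator
floor is unavoidable; samples under the floor are excluded, not clamped).

### Dynamic thresholding and pruning

Within each sliding window of `e_s`, for each `z` in a grid (default 2.0 to
10.0 in steps of 0.5) the threshold `ε = μ + zσ` (population σ) is scored by
the percent decrease in window mean and sd when strict exceedances are
excluded, divided — in the default penalized form — by
`(#points above + #runs above²)`. Ties break toward larger `z` (fewer
anomalies); a window with σ = 0, or with no exceedance at any grid point,
contributes nothing. Exceedance runs are pruned by the sorted-maxima rule:
descending peaks `m_1 ≥ … ≥ m_k` followed by the largest error outside all
runs, percent drops `d_i = (m_i − m_{i+1})/m_i`, survivors are the runs at
or above the last `d_i > p` (default p = 0.10); if no drop exceeds `p`, all
runs are reclassified as normal.

Two composition choices required care on smooth (EWMA) error series:

* **Pruning scope.** Pruning is applied *per window* during detection (each
  window's runs against its own error landscape — the incremental stepping
  of the source method) and then once more *globally* over the merged
  intervals (`prune_scope="both"`, the default). Global-only pruning keeps
  long tails of tiny peaks, whose relative gaps near zero are always large;
  window-only pruning keeps sub-baseline wiggles flagged in quiet periods
  that no global view would call anomalous.
* **Shoulder exclusion.** When the global pass looks for the "largest error
  outside all intervals", the samples within one smoothing span of a flagged
  run are excluded (`exclusion_pad`): they are the EWMA's own relaxation
  tail, and treating them as nominal background makes the drop to
  `m_{k+1}` vanish for exactly the strongest true events. The pure
  `prune_anomalies` operation keeps pad = 0 by default.

Window geometry is scale-dependent and exposed in config: a window must
contain an entire anomalous epoch *plus* many smoothing spans of background
(otherwise the window statistics are bimodal and `max < μ + 2σ`, so nothing
can be flagged). The benchmarks use 128 s windows with 50% overlap on a
~7 min error series; the dataclass default (2048 samples) suits shorter
series. The static baseline flags strict exceedances of one global
`mean + k·sd` bar (k = 2).

Detection is causal: a streaming variant processes the test segment in
chunks (forecast windows, the EWMA one-value state, and threshold windows
each complete as their inputs arrive) and is asserted bit-identical to the
batch path.

### Video path

Desk-scale frames (default 64×64, tests use 16×16) are stacked into
`temporal_depth`-frame volumes and reconstructed by a dense autoencoder
(two tanh encoder layers, mirrored decoder, Adam on MSE, seeded). This
replaces a convolutional-LSTM autoencoder: without a deep-learning framework
in the environment a faithful conv-LSTM is impractical, and for the
downstream math only the per-frame error profile matters. Per-frame errors
sum pixel-wise errors (squared by default; absolute available), averaged
over every stride-1 volume containing the frame. The regularity score is
`s(t) = 1 − (e(t) − min e)/max e`, invariant to positive rescaling of the
errors; a constant error series scores fully regular. The score series then
runs through the identical forecasting/thresholding path, and video
intervals convert to the SEEG time base via `fs/fps` for pooling.

### Evaluation

Detections are pooled by union-merge (channels of a patient, then
modalities). Event matching uses the any-overlap rule by default (an IoU
rule is available): a predicted interval overlapping any truth event is a
true positive; a truth event overlapped by any prediction is detected. PPV
and sensitivity are percentages; F1 is the harmonic mean of the proportions.
A condition with no predictions reports PPV as *undefined*, not 0 — a
detector that stays silent has no precision to speak of. Summaries report
mean ± SEM per condition with undefined values excluded and counted.

## The synthetic world

The generator produces what the pipeline's assumptions require of real EMU
data, with parameters chosen for clinical plausibility:

* **Background**: band oscillations (two spectral "families" — theta/alpha
  vs delta/beta weighted — supporting crossover experiments), each waxing
  and waning under a lognormal Ornstein-Uhlenbeck envelope (log-sd 1.1,
  τ = 35 s: rhythms genuinely come and go); AR(1) noise with a wobbling
  floor (log-sd 0.3, τ = 45 s); and a minutes-scale global amplitude state
  (log-sd 1.2, τ = 150 s) standing in for vigilance changes and movement
  bouts. The episodic, right-skewed character of these envelopes is what
  defeats a single global threshold.
* **Events**: impulse trains at 4 Hz convolved with a biphasic
  (derivative-of-Gaussian) kernel plus a sinusoidal wave component,
  amplitude ramping over the first 30% of the event, with cycle-to-cycle
  amplitude/timing jitter and 12% superimposed "low-voltage fast activity".
  The jitter and fast activity are what keep events unpredictable to a
  well-fit linear model — a purely deterministic rhythm is one-step
  forecastable and would vanish from the error series. Events render at
  full amplitude (default 5× background RMS) on the patient's focus channel
  and attenuated (×0.25-0.5) elsewhere, the spatial falloff any multi-lead
  implant shows. Inter-event gaps are minutes-scale. This is a stand-in
  waveform family, not a biophysical model.
* **Regularity traces**: baseline near 1 with folded-normal noise; true
  events drop `s` by 0.8 and nuisance dips (nurse-visit-like) by 0.35, both
  with seconds-scale onsets and erratic within-dip fluctuation; nuisance
  dips are deliberately excluded from truth labels so false-positive
  behavior is measurable.

What a green benchmark does **not** establish: performance on real SEEG
(electrode artifacts, montage effects, true ictal electrophysiology are all
absent), behavior at 512 Hz/hours-long scale (the benchmark runs 10 min at
256 Hz for CPU speed; 512 Hz is available via config), or the reported
clinical accuracy numbers — those were measured on undeposited patient
recordings and are reproduced here only directionally (dynamic-vs-static
PPV, crossover false-positive inflation, multimodal sensitivity gain) plus
in reconstruction quality (synthetic SEEG MAPE lands at 0.5-0.9%).

Two benchmark variants reflect two regimes: the default (`run_benchmark`,
gain-5 events) measures event recovery, crossover, and pooling; the
drifting-noise-floor variant (`run_drift_benchmark`, gain-2.5 "subtle"
events) measures the dynamic-vs-static PPV direction, because with towering
events the global baseline's sd is event-dominated and the static bar
trivially clears the background — the static threshold's weakness only
shows when seizures are not the loudest thing in the recording.

## Numerical and degenerate-case conventions

Population (ddof = 0) standard deviations throughout the thresholding math;
strict exceedance (`e_s > ε`); values exactly at ε belong to neither the
excluded nor the remaining set. Half-open `[start, end)` intervals, 0-based,
everywhere; merging tolerates a configurable gap (default 0). Constant
windows, constant channels, empty interval lists, and all-below-floor MAPE
each have pinned behaviors (no-anomaly decision, all-zero scaling, empty
output, explicit undefined-metric error). Seeds: every stochastic component
takes an explicit seed; all generators are pure functions of
(parameters, seed), and training is reproducible run-to-run single-threaded.

## Known limitations

* The forecaster is univariate per channel; no cross-channel model.
* The dense video autoencoder ignores spatial locality; adequate at 64×64,
  not a substitute for a convolutional model at 480p.
* Event-level any-overlap scoring counts a single long detection spanning
  two seizures as one true positive but two detected events; latency is not
  scored.
* The pruning rule is order-statistics-based and can keep a lone large
  artifact that resembles an isolated event; on the benchmark this costs
  the dynamic detector a few points of PPV, consistent with the method's
  known behavior.
* MAPE on zero-crossing signals depends on the denominator floor; values
  are comparable within this package, not across conventions.
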