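# Methods

`pulsecast` predicts one continuously sampled physiological waveform from a
paired, easier-to-measure one — arterial blood pressure (ABP) from a
photoplethysmogram (PPG), or intracranial pressure (ICP) from ABP.  Both
signals are quasi-periodic pulse trains coupled through the cardiovascular
system, with a variable time lag, smoothing, and mild static nonlinearity
between them, on top of respiratory modulation and per-sensor artifacts.
This note records the model, the choices made where the design was open,
and what the synthetic experiments do and do not demonstrate.

## Signal model and preprocessing

A trace is a uniformly sampled 1-D sequence `s` with sampling rate `fs`.
Before modeling, three offline stages clean the measured source:

1. **Spike removal.** Samples adjacent to first differences larger than
   `k = 6` times the median absolute deviation (MAD) of all first
   differences are flagged (runs widened by 2 samples) and replaced by a
   cubic spline through the unflagged neighbours.  The MAD rule is
   scale-free; a constant trace (MAD = 0) passes through unchanged, and a
   trace with more than half its samples flagged is rejected as unusable.
2. **Baseline-drift removal.** The baseline is the mean of grayscale
   opening and closing with a flat structuring element of
   `round(1.5 s x fs)` samples (1.5 s exceeds one cardiac cycle at resting
   heart rates), subtracted from the signal.  Averaging opening and closing
   treats peaks and troughs symmetrically, so pulse amplitude is unbiased.
   Note the estimator is a *mid-range* tracker: on an asymmetric pulse
   train the output retains a constant offset of roughly half an amplitude.
   That offset is DC and is removed by the next stage.
3. **Band-pass.** A zero-phase (forward-backward) Butterworth filter,
   order 4, passband 0.5-10 Hz.  Zero-phase application matters because
   the method's whole point is waveform and phase fidelity.

Each stage preserves length.  Reapplying a stage changes the interior of
the signal (one structuring-element span away from the record ends) by
less than 1% RMS for in-band signals; broadband noise re-entering the
filter transition band, respiratory amplitude modulation entering the
envelope estimate, and the trailing-edge morphological transient (a record
usually ends mid-beat) all break exact idempotency at the few-percent
level.  The tests assert the interior, in-band statement.

## Composite features

The denoised signal is segmented into cardiac cycles delimited
trough-to-trough.  Troughs are local minima with minimum separation
`60 fs / hr_high` samples and prominence at least 0.25x the interquartile
amplitude range (defaults `hr_range = (40, 180)` bpm); each consecutive
trough pair contains exactly one peak, the maximum between them.  A guard
rejects segmentations in which most cycles contain more than one
comparably prominent maximum — the signature of a dominant rhythm outside
the configured heart-rate range.

Per cycle `i` with opening trough `t_v,i`, peak `t_p,i` and boundary
`t_b,i := t_v,i`:

| feature | definition | units |
|---|---|---|
| amplitude | `s[t_p,i] - s[t_v,i]` | signal units |
| rise time | `(t_p,i - t_v,i)/fs` | s |
| fall time | `(t_b,i+1 - t_p,i)/fs` | s |
| pulse width | rise + fall (= `(t_b,i+1 - t_b,i)/fs`) | s |

Defining the boundary as the opening trough makes `width = rise + fall`
hold exactly; width is computed as that sum so the identity is exact in
floating point too.  Durations are in seconds, not samples, so features
are comparable across sampling rates.  First and second derivatives are
central differences scaled by `fs` and `fs^2` (one-sided at the edges;
exact for quadratics).  Cycle features are broadcast piecewise-constant
over each cycle's samples, with nearest-cycle fill before the first and
after the last boundary, giving the point-aligned `T x 7` matrix
`[raw, amplitude, width, rise, fall, d1, d2]`.

## Network

The model maps a `T x 7` window to a `T x 1` prediction through three
subnets composed in order:

* **LFE** — two stride-1 1-D convolutions (kernel 3, zero "same" padding,
  7 → 32 → 64 channels), each followed by ReLU.  No subsampling: temporal
  resolution and phase are preserved.
* **TRN** — two stacked bidirectional LSTM layers, per-direction hidden
  size `h` (default 64); forward and backward states are concatenated to
  width `2h` per step.
* **GRA** — one multi-head scaled-dot-product self-attention block over
  the whole window (4 heads, `d_k = 2h/4`, no causal mask), heads
  concatenated and projected back to `2h`.  The block is applied in the
  standard residual form, `out = H + Attn(H) W_O`: the attention output is
  a correction on top of the recurrent representation.  This matters in
  practice — with near-uniform initial attention weights the non-residual
  form outputs each window's time-average, erasing temporal structure
  (measured: the ratio of across-time to total standard deviation drops
  from 0.32 to 0.002 through the block at initialization) and stalling
  early training on a predict-the-mean plateau.
* **Readout** — one affine map shared across time steps, `2h → 1`.

No positional encoding is added; the recurrent subnet precedes attention
and supplies order information.  Initialization: fan-in uniform for
convolutions and linear maps, per-gate orthogonal blocks for the recurrent
matrices, forget-gate bias offset +1.  All weights are float64 numpy
arrays; a forward pass with fixed weights is bit-reproducible.

The network, its backpropagation and the AdamW optimizer are implemented
in this package on a small reverse-mode autodiff engine
(`pulsecast.autodiff`).  The three non-generic primitives — the LSTM
direction, the im2col unfold behind the convolutions, and the one-sided
periodogram — have hand-derived adjoints, each verified against central
finite differences in the test suite (worst relative error ~1e-8 through
the full composed model).

## Training and objective

Windows of `T = 700` samples, stride `S = 100` (defaults; the reduced
protocol below uses 200/50), batch 32, AdamW (default lr 1e-3, weight
decay 1e-2), global gradient-norm clipping at 1.0 — the standard
stabilizer for recurrent nets.  Inputs and target are z-scored per channel
with statistics fitted on the training partition only; all splits
(train/test, k-fold blocks) are contiguous in time because overlapping
windows would leak across a shuffled split.  Metrics are always computed
on the denormalized, physical-unit scale.

The default objective is plain MSE per window.  A composite objective is
available:

    L = L_MSE + lambda_D * L_D + lambda_PSD * L_PSD + lambda_rho * L_rho

with `L_D` the summed squared difference of first differences, `L_PSD` the
squared L2 distance between one-sided periodograms (`|rfft|^2 / T`), and
`L_rho = 1 -
Pearson(pred, target)` (defined as 1 with a warning when either sequence
has zero variance).  Default weights 0.1 / 0.01 / 0.1; all-zero weights
reduce the objective to MSE exactly.

## Inference and fusion

The trained model slides across the record with the training window and
stride; overlapping window predictions are fused by a Hann-tapered
weighted average whose weights are renormalized to sum to one at every
covered sample.  The taper is evaluated on interior points only so every
weight is strictly positive: single-window regions pass through unchanged
and fusing untouched windows reconstructs the covered range to < 1e-9.
The trailing samples beyond the last complete window are reported as
uncovered rather than padded, and evaluation is restricted to the covered
range.

## Evaluation

RMSE, MAE and R^2 in their textbook forms; improvement deltas between a
raw-input run (`s`) and a preprocessed run (`x`):

    dRMSE% = 100 (RMSE_s - RMSE_x) / RMSE_s,   likewise dMAE%,
    dR^2   = R^2_x - R^2_s  (a signed difference, not a percentage);

and Bland-Altman agreement: differences `d = prediction - reference`,
bias = mean(d), SD with denominator n-1 (conventional for limits of
agreement), 95% limits of agreement `bias +/- 1.96 SD`.

## Synthetic data

The simulator generates what the pipeline needs to be verifiable without
clinical recordings.  The clean source is a train of per-beat templates —
raised-cosine rise over a configurable fraction of the period (default
0.3), smooth exponential-style decay, optional dicrotic-notch bump —
placed at onsets whose periods jitter around `60/hr_bpm` (default 70 bpm,
4% jitter), amplitude-modulated by a respiratory sinusoid (0.25 Hz, 15%
depth).  The record opens with the tail of a virtual previous beat so the
first trough is an interior minimum a detector can find.  Sensor artifacts
are added per channel: slow drift (0.05 Hz plus a linear trend), Poisson
spike artifacts, white noise.

The target is a known transfer of the *clean* component: integer-sample
delay (default 0.2 s), first-order exponential smoothing (tau = 50 ms),
gain, a mild quadratic term (coefficient 0.1), plus independent noise.
Artifacts are sensor-local — a paired instrument measures the same
physiology, not the first sensor's motion spikes — which is also what
makes the denoising stage consequential for prediction quality.  All
randomness derives from one root seed; regenerating from a dataset
manifest reproduces every file byte-identically.

What the simulator does **not** emulate: beat-morphology variability
beyond amplitude/period modulation, non-stationary transfer (posture or
autoregulation changes), inter-subject variability, sensor saturation.
Passing the synthetic recovery tests therefore shows the pipeline can
learn a stationary delay-smoothing-nonlinearity transfer under realistic
artifact levels; it does not certify clinical accuracy on real PPG/ABP/ICP
cohorts.

## Reduced-scale study conditions

The end-to-end experiments (test suite and `scripts/acceptance.py`) use
problem sizes chosen so the whole study runs comfortably on one CPU: 60 s
of 50 Hz paired data per seed, 80/20 contiguous split, window 200 /
stride 50, batch 32, `h = 32`, 30 epochs, AdamW lr 5e-3 with clip 1.0,
plain MSE, five seeds.  The preprocessed arm runs
denoise → featurize → train; the ablation control feeds the unprocessed
raw source as a single channel — the same raw-versus-preprocessed contrast
the improvement deltas quantify.  A persistence baseline (best train-fit
affine rescaling of the source used directly as the prediction) anchors
the R^2 scale: the transfer's delay and smoothing keep it near zero while
the trained network reaches ~0.97-0.99.

## Numerical choices and degenerate inputs

* float64 throughout; deterministic given seeds (single-threaded BLAS is
  pinned in the test harness for speed, not correctness).
* Zero-variance channels in the normalizer get scale 1 with a warning;
  zero-variance sequences in the correlation loss define rho := 0.
* R^2 on a zero-variance target is an error, not a number.
* Constant traces: despiking passes them through; segmentation rejects
  them.
* Checkpoints store the config plus all weights; `load(save(m))`
  reproduces forward outputs exactly.

## Known limitations

* The morphological baseline is a mid-range estimator; asymmetric pulse
  trains keep a DC offset until the band-pass stage (see above).
* Cycle features depend on segmentation quality; heavily corrupted
  signals should be denoised first (the pipeline order does this).
* The evaluation restricts to window-covered samples; up to `S - 1`
  trailing samples of a record are never scored.
* Training the full-size configuration (h = 64, window 700, 100 epochs)
  in pure numpy is possible but slow; the package targets method fidelity
  and desk-scale experiments, not GPU-scale throughput.
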