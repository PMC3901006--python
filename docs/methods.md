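# Methods

## Signal model and scope

`vsdikit` treats one experimental *trial* as a movie `data[row, column,
frame]` of raw fluorescence counts with a sampling rate, a 0-based
`onset_frame` (the first post-stimulus frame; frames `[0, onset_frame)` are
the pre-stimulus "frames 0" window), and an identity (session date,
experiment number, trial number, condition code; condition 0 is reserved
for blank trials).  Trials are persisted as 4D NIfTI-1 volumes with axes
(X = column, Y = row, Z = 1, T), float32 voxels, the frame period in
`pixdim[4]` and the onset time in `toffset`; the filename is the single
source of trial identity (no sidecar database).  All trials of a session
must share dimensions, sampling rate and onset — the precondition for
blank averaging and for one design matrix shared across trials.

Proprietary camera formats, motion, vascular artifacts and source-separation
methods are out of scope.

## Blank-subtraction workflow

Per stimulated trial: (1) divide every pixel by its mean over the frames-0
window, making the pre-stimulus mean exactly 1; (2) subtract the pointwise
mean of the session's blank trials; (3) remove, per pixel, the straight
line through the pre-stimulus mean and the mean of the last `end_window`
frames (anchored at the window-centre times), so both window means are
exactly 0 afterwards.  `end_window` defaults to the length of the
pre-stimulus window.

Two choices here were genuinely open:

* blanks are frames-0 divided **before** averaging, so the blank estimate
  is formed in fractional units and baseline heterogeneity across trials
  cannot bias it;
* detrending anchors the line on the two window means rather than
  regressing on all frames — it implements literally "return to baseline at
  the end" and leaves a zero-mean pre-stimulus window untouched.

Pixels with non-positive baseline abort by default; a `mask_nonpositive`
flag turns them into NaNs instead (they are then excluded, with a count,
from ROI averages).

## Response-shape family

The response prototype r(t; α₁..α₈) is piecewise in s = t − α₁:
0 for s ≤ 0; a half-cosine dip to −α₇ over (0, α₂]; a half-cosine rise
from −α₇ to 1 over the next α₃; a plateau at 1 for α₄; a half-cosine fall
from 1 to −α₈ over α₅; a half-cosine recovery to 0 over α₆; 0 afterwards.
The rise and fall branches are

  (1−α₇)/2 − ((1+α₇)/2)·cos(π u/α₃)  and  (1−α₈)/2 + ((1+α₈)/2)·cos(π u/α₅),

the unique coefficients for which every branch matches its neighbours'
endpoints, so the curve is continuous.  Zero-duration segments are skipped
(their half-open interval is empty); a nonzero depth therefore requires a
nonzero duration for its segment (α₇ > 0 needs α₂ > 0, α₈ > 0 needs
α₆ > 0) or the curve steps at the skipped boundary.  Durations are in
seconds, depths dimensionless in [0, 1].

The library sweeps the Cartesian product of per-parameter grids
(`(min, max, n_steps)`; the midpoint when `n_steps = 1`), capped at 100 000
combinations, dropping all-zero rows.  The signal basis Xₛ is the first L
right singular vectors of the **uncentered** library (orthonormal, sign
fixed so each column's largest entry is positive): uncentered because the
shapes' constant component must stay in the signal block rather than leak
into the baseline coefficient; a `center=True` flag gives conventional PCA
for comparison.  By default L is the smallest number of components
capturing 99 % of the library's squared-singular-value energy; it can be
set explicitly.  Shape regressors are built on the onset-shifted time grid
and are therefore zero before the stimulus.

## Noise model and its estimation

The noise block Xₙ holds a decaying exponential e^(−t/τ) (dye bleaching)
and sine/cosine pairs per oscillation frequency — the first (heartbeat)
frequency with `n_harmonics` harmonics (default 2), later peaks with one.

τ and the heartbeat frequency are estimated from the spatially averaged
blank timecourse.  τ is a grid search (default 50 log-spaced values,
0.1×–10× the trial duration, ≈10 % spacing) minimising the residual of a
constant + exponential least-squares fit; the heartbeat frequency is the
largest periodogram ordinate of the exponential-removed residual within a
configurable band (default 1–15 Hz), ties toward the lower frequency.
Because a strong oscillation biases the plain exponential fit by about one
grid step, the two are refined jointly: the grid search is repeated with a
sine/cosine pair at the detected frequency included in the fit, and the
frequency re-read from the refined residual.  A flat residual (constant or
purely exponential input) raises "no oscillation found" rather than
returning an arbitrary frequency.

Additional spectral peaks are local maxima of the amplitude spectrum
exceeding median + z·MAD of all local-maximum heights (default z = 8),
excluding DC, user bands, and frequencies within one resolution bin of an
already-accepted stronger peak.  The threshold rule is this package's
choice; z = 8 keeps white noise below threshold in ≥ 95 % of runs.

The design matrix is assembled in fixed column order — constant,
exponential, Fourier pairs, shape components — and construction fails (with
the condition number and the offending columns) on rank deficiency or on
any harmonic at or above Nyquist.

## Per-pixel fit, ΔF/F, diagnostics

Fitting is ordinary least squares through one reduced QR factorisation of X
shared by all pixels; no explicit inverse or pseudo-inverse is formed, and
a rank-deficient design is refused rather than silently pseudo-solved.
Denoised ΔF/F = (y − X₀β₀ − Xₙβₙ)/β₀ by default ("centred", fluctuating
around 0 so it reads directly as fractional change); the variant that keeps
the constant term is available with `centered=False`.  Pixels with β₀ ≤ 0
abort or are masked NaN, as in the blank pipeline.

The Durbin–Watson statistic DW = Σ(eₜ−eₜ₋₁)²/Σeₜ² is computed per pixel
(NaN for all-zero residuals, where it is undefined).  A pixel is "white"
when DW lies in configurable bounds, default (1.5, 2.5) — roughly ±4
standard deviations of DW around 2 for the 220-frame trials used here;
exact small-sample p-values are out of scope.  The whiteness fraction is an
a-posteriori model-validity indicator: on the reference synthetic session
the correctly specified model leaves ≈ 99.7 % of pixels white, and removing
the heartbeat regressors alone collapses the fraction to ≈ 0.

The heartbeat-contribution map is √(β_sin² + β_cos²) summed over heartbeat
harmonics and divided by β₀ — i.e. in fractions of baseline; normalising by
β₀ makes maps comparable across pixels with different illumination.

## Synthetic sessions and ground truth

The generator emulates a heartbeat-triggered awake-primate VSDI session as
a multiplicative model: every component scales a smooth positive baseline
field F₀ (Gaussian-smoothed white noise, affine-rescaled to the target mean
and spatial CV),

  F = F₀·[1 + b·e^(−t/τ) + Σ aₖ·sin(2πfₖt + φₖ) + c·A·r(t−t_onset)] + F₀·σ·η,

with A a raised-cosine radial bump (1 at the centre, 0 at the radius) and η
i.i.d. standard normal.  This is the structure under which frames-0
division and β₀ normalisation are exact, so recovery tests have closed-form
expectations.  The heartbeat phase is drawn per trial with a small standard
deviation around 0 (default 0.1 rad) because acquisition is
heartbeat-triggered; extra oscillations get uniform random phases.  Each
trial uses its own seeded substream, so any trial is reproducible in
isolation, and configurations whose components could push intensities
negative are rejected.

Reference conditions (the package defaults): 16×16 pixels × 220 frames at
110 Hz (the camera's native 512×512 downscaled to keep simulations small),
onset at frame 22, 6 conditions × 10 trials + 20 blanks, baseline
4000 counts with 10 % spatial CV, bleaching 3 % with τ = 1 s, heartbeat
2.5 Hz at 0.5 % of baseline, evoked amplitudes 0.10–0.50 % across
conditions, noise σ = 0.1 % per pixel per frame.  Magnitudes follow what is
typical of awake-primate VSDI (fractional components 10⁻³–10⁻²; the evoked
signal smaller than the heartbeat artifact); τ is short enough to be
identifiable within a 2 s trial.  The generator does **not** emulate vessel
patterns, motion, respiration drift across trials, camera saturation or
photon statistics — passing recovery tests therefore shows correctness of
the estimation machinery under the model's own assumptions, not robustness
to every artifact of real recordings.

## Numerical choices and degenerate inputs

* All intermediate arithmetic in float64; NIfTI storage in float32 (the
  round-trip is exact at that precision).
* Binning drops remainder rows/columns/frames so block means stay exact;
  the onset frame maps to ⌊onset/k⌋ and the result must keep at least one
  pre-stimulus frame.
* Rank checks compare singular values against `max(shape)·eps` of the
  largest; the QR diagonal is re-checked at fit time for externally built
  matrices.
* R² is clipped to [0, 1]; a zero-variance pixel gets R² = 0.
* Tie-breaks: periodogram argmax takes the lowest frequency; PCA sign fix
  takes the largest-magnitude entry positive.

## Known limitations

Inference on β (standard errors, autocorrelation-corrected tests) is not
provided — the Durbin–Watson screen is a diagnostic, not a test with
calibrated size.  The GLM assumes one design matrix for all trials of a
session; per-trial noise frequencies (e.g. drifting heart rate) are not
modelled.  The blank pipeline's noise floor scales with the number of
blanks and pixels averaged; its leave-one-out mode exists precisely to
evaluate that floor on blanks themselves.
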