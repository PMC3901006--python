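"""Per-pixel GLM denoising of a full session, with diagnostics.

Each pixel's raw timecourse is regressed on [constant | bleaching
exponential + heartbeat Fourier pairs | shape-PCA basis]; the denoised
dF/F removes the fitted noise and normalises by the baseline coefficient.
Durbin-Watson statistics of the residuals validate the model a posteriori.
"""

import numpy as np

from vsdikit import SynthConfig, generate_session, whiteness_report
from vsdikit import session as sess
from vsdikit.postprocess import (
    condition_average, disk_roi, heartbeat_contribution_map,
)

cfg = SynthConfig(seed=0)
trials, truth = generate_session(cfg)

noise = sess.estimate_noise(trials)
design = sess.build_session_design(cfg.T, cfg.sampling_rate,
                                   cfg.onset_frame, noise)
print(f"design matrix: {design.n_regressors} regressors "
      f"({design.noise_idx.size} noise, {design.signal_idx.size} signal)")

fits = sess.fit_session(trials, design)
roi = disk_roi((cfg.H, cfg.W), cfg.roi_center, 2.0)
a_roi = truth.spatial_profile[roi.mask].mean()
dffs = [fits[t.meta.trial_number].dff for t in trials]
codes = [t.meta.condition_code for t in trials]

print("condition-averaged ROI responses (10 trials each):")
for cond in range(1, cfg.n_conditions + 1):
    mean, sd, n = condition_average(dffs, codes, cond, roi)
    true_peak = cfg.response_amplitudes[cond - 1] * a_roi
    corr = np.corrcoef(
        mean, truth.response_shape * true_peak)[0, 1]
    print(f"  condition {cond}: peak {100*mean.max():.3f}% dF/F "
          f"(true {100*true_peak:.3f}%), correlation {corr:.3f}")

hb = heartbeat_contribution_map(next(iter(fits.values())), design)
print(f"heartbeat map at ROI: {100*hb[roi.mask].mean():.3f}% of baseline "
      f"(generated {100*cfg.heartbeat_amplitude:.3f}%)")
white = np.mean([whiteness_report(f)[1] for f in fits.values()])
print(f"residual whiteness (DW in [1.5, 2.5]): {100*white:.1f}% of pixels")
# Correlations near 1 and a whiteness fraction near 100% mean the model
# explains both the signal and the structured noise at every pixel.
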