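"""Estimate the noise model from blank trials.

The bleaching time constant tau comes from a grid search of a
constant + exponential fit to the spatially averaged blank timecourse
(refined jointly with the heartbeat); the heartbeat frequency is the
dominant periodogram peak of the exponential-removed residual; additional
spectral peaks are screened with a median + z*MAD rule.
"""

from vsdikit import SynthConfig, generate_session, spectral_peaks
from vsdikit.session import blank_mean_timecourse, estimate_noise

cfg = SynthConfig(seed=0)
trials, _ = generate_session(cfg)

spec = estimate_noise(trials)
print(f"bleaching tau: {spec.tau:.3f} s   (generator used {cfg.bleach_tau} s)")
print(f"heartbeat: {spec.oscillation_freqs[0]:.2f} Hz "
      f"(generator used {cfg.heartbeat_freq} Hz), "
      f"{spec.n_harmonics} harmonics in the model")

tc = blank_mean_timecourse(trials)
peaks = spectral_peaks(tc, cfg.sampling_rate, z_threshold=8.0)
print(f"spectral peaks above threshold: "
      f"{[f'{p:.2f} Hz' for p in peaks]}")
# Expect the heartbeat plus a low-frequency peak where the bleaching decay
# leaks into the spectrum (peak screening sees the raw timecourse); the
# exponential regressor, not a Fourier pair, accounts for the latter.
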