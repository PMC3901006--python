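"""Seeded synthetic optical-imaging sessions with ground truth.

The generator emulates a trial-based mesoscopic voltage-sensitive dye
imaging session: a smooth positive baseline image modulated multiplicatively
by dye bleaching (decaying exponential), a heartbeat oscillation whose phase
is near-locked across trials (acquisition is heartbeat-triggered), optional
extra oscillations, a condition-dependent evoked response with a radial
spatial profile and a parametric temporal shape, and white sensor noise:

    F(x,y,t) = F0(x,y) * [1 + b*exp(-t/tau)
                            + sum_k a_k*sin(2*pi*f_k*t + phi_k)
                            + c_cond * A(x,y) * r(t - t_onset)]
               + F0(x,y) * sigma * eta(x,y,t)

All fractional components scale the baseline F0, the structure under which
frames-0 division and baseline-coefficient normalisation are exact, so
recovery tests have closed-form expectations.

Default fractional amplitudes (bleaching a few percent, heartbeat and evoked
responses in the 1e-3 range, noise 1e-3 per pixel per frame) reflect the
magnitudes typical of awake-primate VSDI recordings.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from vsdikit.data_model import TrialMeta, TrialStack
from vsdikit.model_builder import ShapeParams, response_shape

__all__ = ["SynthConfig", "GroundTruth", "generate_session", "paper_dataset_config"]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic session.

    Amplitudes (``bleach_amplitude``, ``heartbeat_amplitude``, entries of
    ``response_amplitudes`` and ``extra_oscillations``, ``noise_sd``) are
    fractions of the local baseline F0.  ``heartbeat_phase_jitter`` is the
    standard deviation (radians) of the per-trial heartbeat phase around 0;
    trials are heartbeat-triggered, so phases are near-aligned by default.
    """

    H: int = 16
    W: int = 16
    T: int = 220
    sampling_rate: float = 110.0
    onset_frame: int = 22
    n_conditions: int = 6
    trials_per_condition: int = 10
    n_blanks: int = 20
    baseline_mean: float = 4000.0
    baseline_spatial_cv: float = 0.1
    bleach_amplitude: float = 0.03
    bleach_tau: float = 1.0
    heartbeat_freq: float = 2.5
    heartbeat_amplitude: float = 5e-3
    heartbeat_phase_jitter: float = 0.1
    extra_oscillations: tuple[tuple[float, float], ...] = ()
    response_amplitudes: tuple[float, ...] = (
        1.0e-3, 1.8e-3, 2.6e-3, 3.4e-3, 4.2e-3, 5.0e-3)
    shape_params: ShapeParams = field(
        default_factory=lambda: ShapeParams(
            alpha1=0.05, alpha2=0.0, alpha3=0.15, alpha4=0.3,
            alpha5=0.25, alpha6=0.25, alpha7=0.0, alpha8=0.15))
    roi_center: tuple[float, float] = (8.0, 8.0)
    roi_radius: float = 6.0
    noise_sd: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "response_amplitudes",
                           tuple(self.response_amplitudes))
        object.__setattr__(self, "extra_oscillations",
                           tuple((float(f), float(a))
                                 for f, a in self.extra_oscillations))
        if len(self.response_amplitudes) != self.n_conditions:
            raise ValueError(
                f"response_amplitudes has {len(self.response_amplitudes)} "
                f"entries; expected n_conditions={self.n_conditions}"
            )
        amps = (self.bleach_amplitude, self.heartbeat_amplitude, self.noise_sd,
                *(a for _, a in self.extra_oscillations),
                *self.response_amplitudes)
        if any(a < 0 for a in amps):
            raise ValueError("amplitudes and noise_sd must be >= 0")
        if self.bleach_tau <= 0:
            raise ValueError("bleach_tau must be positive")
        if self.heartbeat_freq >= self.sampling_rate / 2:
            raise ValueError("heartbeat_freq must be below Nyquist")

    @property
    def n_trials(self) -> int:
        return self.n_conditions * self.trials_per_condition + self.n_blanks


@dataclass
class GroundTruth:
    """Per-trial generative components, for recovery tests.

    ``noise_timecourses`` maps component name ('bleach', 'heartbeat',
    'osc<f>') to the per-trial fractional timecourse; ``response_timecourse``
    is ``c_cond * r(t - onset)`` (zero for blanks); ``spatial_profile`` is
    the radial response profile A(x, y); ``baseline`` is F0(x, y).
    """

    baseline: np.ndarray
    spatial_profile: np.ndarray
    response_shape: np.ndarray              # unit-amplitude r(t - onset)
    condition_codes: np.ndarray             # per trial, 0 = blank
    response_amplitudes: np.ndarray         # per trial c (0 for blanks)
    response_timecourses: np.ndarray        # n_trials x T, c * r(t - onset)
    noise_timecourses: dict[str, np.ndarray]  # name -> n_trials x T
    heartbeat_phases: np.ndarray            # per trial, radians


def _baseline_field(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth positive random field with the target mean and spatial CV."""
    raw = gaussian_filter(
        rng.standard_normal((cfg.H, cfg.W)),
        sigma=max(1.0, min(cfg.H, cfg.W) / 8.0),
        mode="reflect",
    )
    sd = raw.std()
    if sd < 1e-12 or cfg.baseline_spatial_cv == 0:
        return np.full((cfg.H, cfg.W), cfg.baseline_mean)
    field = (raw - raw.mean()) / sd  # zero mean, unit sd
    f0 = cfg.baseline_mean * (1.0 + cfg.baseline_spatial_cv * field)
    return np.clip(f0, 0.05 * cfg.baseline_mean, None)


def _radial_profile(cfg: SynthConfig) -> np.ndarray:
    """Raised-cosine bump: 1 at the ROI center, 0 at and beyond the radius."""
    rows = np.arange(cfg.H)[:, None]
    cols = np.arange(cfg.W)[None, :]
    d = np.hypot(rows - cfg.roi_center[0], cols - cfg.roi_center[1])
    a = 0.5 * (1.0 + np.cos(np.pi * np.minimum(d / cfg.roi_radius, 1.0)))
    return a


def generate_session(cfg: SynthConfig) -> tuple[list[TrialStack], GroundTruth]:
    """Generate all trials of a synthetic session, fully seeded.

    Trial ordering: blanks first (condition 0), then conditions 1..n in
    blocks of ``trials_per_condition``; trial numbers are sequential.  Each
    trial draws from its own random substream (seeded by ``cfg.seed`` and the
    trial index) so any trial is reproducible in isolation.

    Raises ``ValueError`` if the configured fractional components could sum
    below -1 (predicted negative intensities).
    """
    worst = (cfg.bleach_amplitude + cfg.heartbeat_amplitude
             + sum(a for _, a in cfg.extra_oscillations)
             + max(cfg.response_amplitudes, default=0.0))
    if worst >= 1.0:
        raise ValueError(
            "fractional components can sum below -1, predicting negative "
            "intensities; use smaller amplitudes"
        )

    root = np.random.default_rng(cfg.seed)
    f0 = _baseline_field(cfg, root)
    profile = _radial_profile(cfg)
    t = np.arange(cfg.T) / cfg.sampling_rate
    shape = response_shape(t - cfg.onset_frame / cfg.sampling_rate,
                           cfg.shape_params)

    codes = np.concatenate([
        np.zeros(cfg.n_blanks, dtype=int),
        np.repeat(np.arange(1, cfg.n_conditions + 1), cfg.trials_per_condition),
    ])
    n_trials = codes.size
    amps = np.where(codes > 0,
                    np.array((0.0,) + cfg.response_amplitudes)[codes], 0.0)

    bleach = cfg.bleach_amplitude * np.exp(-t / cfg.bleach_tau)
    noise_tc: dict[str, np.ndarray] = {
        "bleach": np.tile(bleach, (n_trials, 1)),
        "heartbeat": np.zeros((n_trials, cfg.T)),
    }
    for f, _a in cfg.extra_oscillations:
        noise_tc[f"osc{f:g}"] = np.zeros((n_trials, cfg.T))

    phases = np.zeros(n_trials)
    response_tc = amps[:, None] * shape[None, :]
    trials: list[TrialStack] = []
    date = _dt.date(2024, 1, 15)
    for k in range(n_trials):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(k + 1,)))
        phase = rng.normal(0.0, cfg.heartbeat_phase_jitter)
        phases[k] = phase
        heart = cfg.heartbeat_amplitude * np.sin(
            2.0 * np.pi * cfg.heartbeat_freq * t + phase)
        noise_tc["heartbeat"][k] = heart
        frac_tc = bleach + heart  # shared over space
        for f, a in cfg.extra_oscillations:
            ph = rng.uniform(0.0, 2.0 * np.pi)
            osc = a * np.sin(2.0 * np.pi * f * t + ph)
            noise_tc[f"osc{f:g}"][k] = osc
            frac_tc = frac_tc + osc

        frac = (1.0 + frac_tc[None, None, :]
                + amps[k] * profile[:, :, None] * shape[None, None, :])
        data = f0[:, :, None] * frac
        if cfg.noise_sd > 0:
            data = data + (f0[:, :, None] * cfg.noise_sd
                           * rng.standard_normal((cfg.H, cfg.W, cfg.T)))
        meta = TrialMeta(
            session_date=date,
            experiment_number=1,
            trial_number=k + 1,
            condition_code=int(codes[k]),
        )
        trials.append(TrialStack(
            data=data, sampling_rate=cfg.sampling_rate,
            onset_frame=cfg.onset_frame, meta=meta))

    truth = GroundTruth(
        baseline=f0,
        spatial_profile=profile,
        response_shape=shape,
        condition_codes=codes,
        response_amplitudes=amps,
        response_timecourses=response_tc,
        noise_timecourses=noise_tc,
        heartbeat_phases=phases,
    )
    return trials, truth


def paper_dataset_config(seed: int = 0, **overrides) -> SynthConfig:
    """Configuration mirroring the distributed VSDI dataset's design.

    6 stimulus conditions (contrast levels) x 10 trials plus 20 blank
    trials — 80 trials total — sampled at 110 Hz, heartbeat-triggered.
    The 512 x 512 camera resolution is downscaled to keep simulations small.
    """
    return SynthConfig(seed=seed, **overrides)
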