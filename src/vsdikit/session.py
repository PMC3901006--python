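"""End-to-end session analysis: noise estimation → model → per-trial fits.

Glue over the elementary operations, working on in-memory trial lists.  The
command-line layer adds file I/O and provenance on top of these functions.
"""

from __future__ import annotations

import numpy as np

from vsdikit.data_model import TrialStack
from vsdikit.glm import FitResult, fit_glm
from vsdikit.model_builder import (
    DesignMatrix,
    NoiseSpec,
    ShapeIntervals,
    build_design_matrix,
    estimate_tau_and_heartbeat,
    generate_shape_library,
    shape_basis,
    shape_time_grid,
    spectral_peaks,
)

__all__ = [
    "blank_mean_timecourse",
    "estimate_noise",
    "build_session_design",
    "fit_session",
]


def blank_mean_timecourse(trials: list[TrialStack]) -> np.ndarray:
    """Spatially averaged timecourse, averaged across the session's blanks."""
    blanks = [t for t in trials if t.meta.is_blank]
    if not blanks:
        raise ValueError("session contains no blank trials")
    return np.mean([b.data.mean(axis=(0, 1)) for b in blanks], axis=0)


def estimate_noise(
    trials: list[TrialStack],
    heart_band: tuple[float, float] = (1.0, 15.0),
    n_harmonics: int = 2,
    tau_grid: np.ndarray | None = None,
    z_threshold: float = 8.0,
    extra_peaks: bool = False,
) -> NoiseSpec:
    """Estimate the noise block from blank trials.

    The bleaching time constant and heartbeat frequency come from the blank
    mean timecourse; with ``extra_peaks=True`` additional spectral peaks
    (outside one resolution bin of the heartbeat harmonics) are appended as
    single-harmonic oscillation regressors.
    """
    tc = blank_mean_timecourse(trials)
    fs = trials[0].sampling_rate
    tau, f_heart = estimate_tau_and_heartbeat(
        tc, fs, tau_grid=tau_grid, heart_band=heart_band)
    freqs = [f_heart]
    if extra_peaks:
        bin_w = fs / tc.size
        exclude = [(h * f_heart - bin_w, h * f_heart + bin_w)
                   for h in range(1, n_harmonics + 1)]
        for f in spectral_peaks(tc, fs, z_threshold=z_threshold,
                                exclude_bands=exclude):
            freqs.append(f)
    return NoiseSpec(
        include_exponential=True,
        tau=tau,
        oscillation_freqs=tuple(freqs),
        n_harmonics=n_harmonics,
    )


def build_session_design(
    n_frames: int,
    sampling_rate: float,
    onset_frame: int,
    noise: NoiseSpec,
    intervals: ShapeIntervals | None = None,
    L: int | None = None,
    energy: float = 0.99,
) -> DesignMatrix:
    """Sweep the shape family, extract the PCA basis, assemble the design.

    Shape regressors are built on the onset-shifted time grid, so they are
    zero before the stimulus.  ``L=None`` keeps the smallest number of
    components capturing ``energy`` of the library's variance.
    """
    intervals = intervals or ShapeIntervals()
    t_shape = shape_time_grid(n_frames, sampling_rate, onset_frame)
    library = generate_shape_library(intervals, t_shape)
    basis = shape_basis(library, L=L, energy=energy)
    return build_design_matrix(
        n_frames, sampling_rate, onset_frame,
        noise=noise, shape_basis_matrix=basis,
    )


def fit_session(
    trials: list[TrialStack],
    design: DesignMatrix,
    stimulated_only: bool = False,
    centered: bool = True,
) -> dict[int, FitResult]:
    """Fit the shared design to each trial; keys are trial numbers."""
    out: dict[int, FitResult] = {}
    for tr in trials:
        if stimulated_only and tr.meta.is_blank:
            continue
        out[tr.meta.trial_number] = fit_glm(tr, design, centered=centered)
    return out
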