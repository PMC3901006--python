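"""Session-level aggregation, method comparison, maps and figures.

All operations consume denoised ΔF/F stacks (from either workflow) plus a
region of interest, and reduce across pixels and/or trials: ROI timecourses,
condition averages with dispersion, trial variability, paired comparison of
two methods, and the spatial map of the heartbeat contribution estimated by
the GLM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from vsdikit.glm import FitResult
from vsdikit.model_builder import DesignMatrix

__all__ = [
    "ROI",
    "disk_roi",
    "roi_timecourse",
    "condition_average",
    "trial_variability",
    "compare_methods",
    "heartbeat_contribution_map",
    "plot_condition_averages",
    "plot_heartbeat_map",
]

log = logging.getLogger(__name__)


@dataclass
class ROI:
    """A labelled boolean pixel mask over the session's field of view."""

    mask: np.ndarray
    label: str = "roi"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2D (H x W)")
        if not self.mask.any():
            raise ValueError("ROI mask has no pixels")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def disk_roi(
    shape: tuple[int, int], center: tuple[float, float], radius: float,
    label: str = "roi",
) -> ROI:
    """Disk-shaped ROI: pixels within ``radius`` of ``center`` (row, col)."""
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    d = np.hypot(rows - center[0], cols - center[1])
    return ROI(mask=d <= radius, label=label)


def _stack_data(stack) -> np.ndarray:
    if isinstance(stack, np.ndarray):
        return stack
    return np.asarray(stack.data)


def roi_timecourse(stack, roi: ROI) -> np.ndarray:
    """Unweighted mean over the ROI's pixels, per frame (NaN pixels excluded)."""
    data = _stack_data(stack)
    if data.shape[:2] != roi.mask.shape:
        raise ValueError(
            f"stack spatial shape {data.shape[:2]} does not match "
            f"ROI mask {roi.mask.shape}"
        )
    sub = data[roi.mask]                       # n_pixels x T
    n_nan = int(np.isnan(sub).any(axis=1).sum())
    if n_nan:
        log.info("roi_timecourse: excluding %d NaN pixel(s)", n_nan)
    return np.nanmean(sub, axis=0)


def condition_average(
    stacks: list, condition_codes: list[int], condition: int, roi: ROI
) -> tuple[np.ndarray, np.ndarray, int]:
    """Mean and sample sd of ROI timecourses over trials of one condition.

    Returns (mean T-vector, sd T-vector, n).  With a single trial the sd is
    reported as 0 (logged, since dispersion is undefined at n=1).
    """
    if len(stacks) != len(condition_codes):
        raise ValueError("one condition code per stack required")
    tcs = [roi_timecourse(s, roi)
           for s, c in zip(stacks, condition_codes) if c == condition]
    if not tcs:
        raise ValueError(f"no trials with condition {condition}")
    arr = np.array(tcs)
    n = arr.shape[0]
    mean = arr.mean(axis=0)
    if n == 1:
        log.info("condition %d has a single trial; sd reported as 0", condition)
        sd = np.zeros_like(mean)
    else:
        sd = arr.std(axis=0, ddof=1)
    return mean, sd, n


def trial_variability(stacks: list, roi: ROI) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial ROI timecourses and their per-frame dispersion (sample sd)."""
    if not stacks:
        raise ValueError("empty session")
    arr = np.array([roi_timecourse(s, roi) for s in stacks])
    sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(arr.shape[1])
    return arr, sd


def compare_methods(
    denoised_a: list, denoised_b: list,
    condition_codes: list[int], condition: int, roi: ROI,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Condition-mean timecourses of two methods and their RMS difference.

    Returns (2 x T paired timecourses, per-frame difference, RMS difference).
    """
    if len(denoised_a) != len(denoised_b):
        raise ValueError("the two methods must cover the same trials")
    mean_a, _, _ = condition_average(denoised_a, condition_codes, condition, roi)
    mean_b, _, _ = condition_average(denoised_b, condition_codes, condition, roi)
    diff = mean_a - mean_b
    rms = float(np.sqrt(np.mean(diff**2)))
    return np.vstack([mean_a, mean_b]), diff, rms


def heartbeat_contribution_map(fit: FitResult, design: DesignMatrix) -> np.ndarray:
    """Per-pixel fractional heartbeat amplitude estimated by the GLM.

    For each heartbeat harmonic the sine/cosine coefficient pair gives an
    amplitude sqrt(β_sin² + β_cos²); amplitudes are summed over harmonics
    and normalised by the baseline coefficient β0, yielding a map in
    fractions of baseline fluorescence.
    """
    pairs = design.heartbeat_columns()
    if not pairs:
        raise ValueError("design matrix contains no heartbeat regressors")
    b0 = fit.beta[:, :, design.constant_idx[0]]
    total = np.zeros_like(b0)
    for si, ci in pairs:
        total += np.hypot(fit.beta[:, :, si], fit.beta[:, :, ci])
    return total / b0


def plot_condition_averages(
    results: dict[int, tuple[np.ndarray, np.ndarray, int]],
    sampling_rate: float,
    onset_frame: int,
    path=None,
    title: str = "Condition-averaged ΔF/F",
):
    """Timecourse plot with ±1 sd bands, one line per condition."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for cond, (mean, sd, n) in sorted(results.items()):
        t = np.arange(mean.size) / sampling_rate
        line, = ax.plot(t, mean, label=f"condition {cond} (n={n})")
        ax.fill_between(t, mean - sd, mean + sd,
                        color=line.get_color(), alpha=0.2, linewidth=0)
    ax.axvline(onset_frame / sampling_rate, color="k", ls="--", lw=0.8,
               label="stimulus onset")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("ΔF/F")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_heartbeat_map(hb_map: np.ndarray, rois: list[ROI] | None = None,
                       path=None):
    """Spatial map of the fractional heartbeat contribution, ROI contours overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(hb_map, cmap="magma")
    fig.colorbar(im, ax=ax, label="heartbeat amplitude (fraction of baseline)")
    for roi in rois or []:
        ax.contour(roi.mask.astype(float), levels=[0.5], colors="cyan",
                   linewidths=1.0)
    ax.set_title("Heartbeat contribution")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
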