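"""The standard blank-subtraction workflow.

Per trial: divide by the pre-stimulus "frames 0" baseline, subtract the
session's blank-trial average (computed in the same fractional units), and
linearly detrend so the signal returns to baseline by the end of the trial.
The result is a ΔF/F stack centred at 0.

Blank trials are frames-0 divided *before* averaging so that baseline
heterogeneity across trials does not bias the blank estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from vsdikit.data_model import TrialMeta, TrialStack

__all__ = [
    "FractionalStack",
    "frames0_divide",
    "average_blanks",
    "blank_subtract",
    "linear_detrend",
    "run_blank_pipeline",
]


@dataclass
class FractionalStack:
    """Dimensionless H x W x T stack of fractional fluorescence (ΔF/F)."""

    data: np.ndarray
    sampling_rate: float
    onset_frame: int
    meta: TrialMeta | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("fractional stack must be 3D (H, W, T)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]


def frames0_divide(stack: TrialStack, mask_nonpositive: bool = False) -> FractionalStack:
    """Divide every frame by the per-pixel mean of the pre-stimulus frames.

    After division the pre-stimulus frames of every pixel average to exactly
    1.  Pixels whose baseline mean is <= 0 raise by default; with
    ``mask_nonpositive=True`` they are set to NaN instead.
    """
    baseline = stack.data[:, :, : stack.onset_frame].mean(axis=2)
    bad = baseline <= 0
    n_bad = int(bad.sum())
    if n_bad and not mask_nonpositive:
        raise ValueError(
            f"{n_bad} pixel(s) have non-positive pre-stimulus baseline; "
            "pass mask_nonpositive=True to mask them as NaN"
        )
    denom = np.where(bad, np.nan, baseline)
    out = stack.data / denom[:, :, None]
    return FractionalStack(
        data=out,
        sampling_rate=stack.sampling_rate,
        onset_frame=stack.onset_frame,
        meta=stack.meta,
    )


def average_blanks(blanks: list[FractionalStack]) -> FractionalStack:
    """Pointwise arithmetic mean of blank trials (in fractional units)."""
    if not blanks:
        raise ValueError("need at least one blank trial to average")
    shape = blanks[0].shape
    for b in blanks[1:]:
        if b.shape != shape:
            raise ValueError(
                f"blank dimension mismatch: {b.shape} vs {shape}"
            )
    mean = np.mean([b.data for b in blanks], axis=0)
    return FractionalStack(
        data=mean,
        sampling_rate=blanks[0].sampling_rate,
        onset_frame=blanks[0].onset_frame,
        meta=None,
    )


def blank_subtract(trial: FractionalStack, blank_mean: FractionalStack) -> FractionalStack:
    """Frame-by-frame subtraction of the blank average; result is ΔF/F at 0."""
    if trial.shape != blank_mean.shape:
        raise ValueError(
            f"dimension mismatch: trial {trial.shape} vs blank {blank_mean.shape}"
        )
    return FractionalStack(
        data=trial.data - blank_mean.data,
        sampling_rate=trial.sampling_rate,
        onset_frame=trial.onset_frame,
        meta=trial.meta,
    )


def linear_detrend(stack: FractionalStack, end_window: int | None = None) -> FractionalStack:
    """Remove, per pixel, the line through the pre-stimulus and end-window means.

    The line is anchored at the window-centre times: it passes through
    (t̄_pre, mean over frames [0, onset)) and (t̄_end, mean over the last
    ``end_window`` frames).  After subtraction both window means are 0, so
    the timecourse starts and returns to baseline.  ``end_window`` defaults
    to the length of the pre-stimulus window.
    """
    t_total = stack.n_frames
    onset = stack.onset_frame
    if end_window is None:
        end_window = onset
    if end_window < 1:
        raise ValueError("end_window must be >= 1")
    if t_total - end_window < onset:
        raise ValueError(
            f"end window of {end_window} frames overlaps the pre-stimulus "
            f"window [0, {onset}) in a {t_total}-frame trial"
        )
    frames = np.arange(t_total, dtype=np.float64)
    pre_mean = stack.data[:, :, :onset].mean(axis=2)
    end_mean = stack.data[:, :, t_total - end_window:].mean(axis=2)
    t_pre = frames[:onset].mean()
    t_end = frames[t_total - end_window:].mean()
    slope = (end_mean - pre_mean) / (t_end - t_pre)
    intercept = pre_mean - slope * t_pre
    trend = intercept[:, :, None] + slope[:, :, None] * frames[None, None, :]
    return FractionalStack(
        data=stack.data - trend,
        sampling_rate=stack.sampling_rate,
        onset_frame=stack.onset_frame,
        meta=stack.meta,
    )


def run_blank_pipeline(
    trial: TrialStack,
    blanks: list[TrialStack],
    end_window: int | None = None,
    leave_one_out: bool = False,
    mask_nonpositive: bool = False,
) -> FractionalStack:
    """Full standard workflow: frames-0 division, blank subtraction, detrend.

    With ``leave_one_out=True`` and a blank input trial, the trial itself is
    excluded from the blank average (needed when evaluating the pipeline's
    null behaviour on the blanks themselves).
    """
    if not blanks:
        raise ValueError("blank list is empty")
    use = blanks
    if leave_one_out and trial.meta is not None and trial.meta.is_blank:
        use = [b for b in blanks if b.meta != trial.meta]
        if not use:
            raise ValueError("leave-one-out removed the only blank trial")
    frac = frames0_divide(trial, mask_nonpositive=mask_nonpositive)
    blank_mean = average_blanks(
        [frames0_divide(b, mask_nonpositive=mask_nonpositive) for b in use]
    )
    return linear_detrend(blank_subtract(frac, blank_mean), end_window=end_window)
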