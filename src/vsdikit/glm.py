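"""Per-pixel ordinary least squares fitting, ΔF/F denoising and diagnostics.

Each pixel's raw timecourse y is regressed on the shared design matrix
X = [X0 | Xn | Xs] (constant baseline, noise regressors, response-shape
basis).  Fitting uses a single QR factorisation of X reused across all
pixels; no explicit matrix inverse is formed.

Denoising removes the estimated noise contribution and normalises by the
baseline coefficient:  ΔF/F = (y - Xn·βn) / β0, optionally (and by default)
also subtracting the constant contribution so blank-like pixels fluctuate
around zero:  ΔF/F = (y - X0·β0 - Xn·βn) / β0.

The Durbin–Watson statistic of the per-pixel residuals (≈ 2 for white
residuals) serves as an a-posteriori indicator of model validity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from vsdikit.data_model import TrialStack
from vsdikit.model_builder import DesignMatrix

__all__ = ["FitResult", "fit_glm", "denoise", "durbin_watson", "whiteness_report"]


@dataclass
class FitResult:
    """Per-pixel regression output for one trial.

    beta:       H x W x P coefficients (constant, noise, signal blocks);
    residuals:  H x W x T residual timecourses;
    dff:        H x W x T denoised ΔF/F (centred by default);
    r_squared:  H x W coefficient of determination;
    dw:         H x W Durbin–Watson statistics of the residuals.
    """

    beta: np.ndarray
    residuals: np.ndarray
    dff: np.ndarray
    r_squared: np.ndarray
    dw: np.ndarray
    design: DesignMatrix = field(repr=False)
    sampling_rate: float = 0.0
    onset_frame: int = 0


def durbin_watson(residual: np.ndarray) -> float | np.ndarray:
    """Durbin–Watson statistic DW = Σ(e_t - e_{t-1})² / Σ e_t², in [0, 4].

    Accepts a 1D residual vector or an N x T array (statistic per row).
    All-zero residuals yield NaN (the statistic is undefined there).
    """
    e = np.asarray(residual, dtype=np.float64)
    one_d = e.ndim == 1
    e = np.atleast_2d(e)
    if e.shape[-1] < 2:
        raise ValueError("need at least 2 residual samples")
    num = np.sum(np.diff(e, axis=-1) ** 2, axis=-1)
    den = np.sum(e**2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dw = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return float(dw[0]) if one_d else dw


def fit_glm(
    stack: TrialStack,
    design: DesignMatrix,
    centered: bool = True,
    mask_nonpositive: bool = False,
) -> FitResult:
    """Fit the design matrix to every pixel of a trial by least squares.

    A single reduced QR factorisation of X is shared across pixels.  The
    design must be full column rank (construction enforces this; the check
    here guards externally built matrices).  Returns coefficients,
    residuals, denoised ΔF/F (see :func:`denoise`), R² and Durbin–Watson
    maps.
    """
    X = design.X
    h, w, t = stack.shape
    if t != X.shape[0]:
        raise ValueError(
            f"trial has {t} frames but design matrix has {X.shape[0]} rows"
        )
    q, r = np.linalg.qr(X, mode="reduced")
    diag = np.abs(np.diag(r))
    if np.any(diag <= np.max(diag) * np.finfo(float).eps * max(X.shape)):
        raise ValueError("design matrix is rank deficient; refusing to fit")

    Y = stack.data.reshape(h * w, t).T          # T x N
    beta = np.linalg.solve(r, q.T @ Y)          # P x N
    fitted = X @ beta
    resid = Y - fitted

    sse = np.sum(resid**2, axis=0)
    sst = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(sst > 0, 1.0 - sse / np.where(sst > 0, sst, 1.0), 0.0)
    r2 = np.clip(r2, 0.0, 1.0)

    p = X.shape[1]
    result = FitResult(
        beta=beta.T.reshape(h, w, p),
        residuals=resid.T.reshape(h, w, t),
        dff=np.empty((h, w, t)),
        r_squared=r2.reshape(h, w),
        dw=durbin_watson(resid.T).reshape(h, w),
        design=design,
        sampling_rate=stack.sampling_rate,
        onset_frame=stack.onset_frame,
    )
    result.dff = denoise(result, stack, design, centered=centered,
                         mask_nonpositive=mask_nonpositive)
    return result


def denoise(
    fit: FitResult,
    stack: TrialStack,
    design: DesignMatrix,
    centered: bool = True,
    mask_nonpositive: bool = False,
) -> np.ndarray:
    """Noise-removed, baseline-normalised ΔF/F.

    As-printed mode (``centered=False``): ΔF/F = (y - Xn·βn) / β0, which
    retains the constant term (values near 1 for blank-like pixels).
    Centred mode (default): additionally subtracts X0·β0, so ΔF/F
    fluctuates around 0 and reads directly as fractional change.

    Pixels with β0 <= 0 raise by default, or become NaN with
    ``mask_nonpositive=True``.
    """
    h, w, t = stack.shape
    X = design.X
    beta = fit.beta.reshape(h * w, X.shape[1]).T     # P x N
    Y = stack.data.reshape(h * w, t).T               # T x N

    b0 = beta[design.constant_idx[0]]
    bad = b0 <= 0
    if bad.any():
        if not mask_nonpositive:
            raise ValueError(
                f"{int(bad.sum())} pixel(s) have non-positive baseline "
                "coefficient; pass mask_nonpositive=True to mask them"
            )
        b0 = np.where(bad, np.nan, b0)

    noise_part = X[:, design.noise_idx] @ beta[design.noise_idx]
    numer = Y - noise_part
    if centered:
        numer = numer - np.outer(X[:, design.constant_idx[0]], b0)
    dff = numer / b0[None, :]
    return dff.T.reshape(h, w, t)


def whiteness_report(
    fit: FitResult, bounds: tuple[float, float] = (1.5, 2.5)
) -> tuple[np.ndarray, float]:
    """Map of pixels whose residuals pass the Durbin–Watson whiteness bounds.

    A pixel is flagged white iff ``low <= DW <= high``.  Returns the boolean
    map and the white fraction over pixels with a defined statistic.
    """
    low, high = bounds
    dw = fit.dw
    valid = np.isfinite(dw)
    white = valid & (dw >= low) & (dw <= high)
    n_valid = int(valid.sum())
    fraction = float(white.sum() / n_valid) if n_valid else float("nan")
    return white, fraction
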