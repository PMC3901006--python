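"""Design-matrix construction for per-pixel GLM denoising.

The design matrix X = [X0 | Xn | Xs] partitions into

* ``X0`` — a single constant column whose coefficient estimates the per-pixel
  baseline fluorescence;
* ``Xn`` — noise regressors: a decaying exponential ``exp(-t/tau)`` for dye
  bleaching and sine/cosine pairs (a truncated Fourier series) for each
  oscillatory component, heartbeat first with optional harmonics;
* ``Xs`` — a signal basis obtained by sweeping a parametric response-shape
  family over user-specified parameter intervals and keeping the first L
  principal directions of the resulting shape library.

The response-shape family r(t; alpha) is a continuous piecewise half-cosine
curve: a latency, an optional initial dip, a rise to a plateau at 1, a fall
into an optional undershoot, and a recovery to 0.

Noise parameters (tau, heartbeat frequency, additional spectral peaks) are
estimated from the spatially averaged timecourse of blank trials.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

__all__ = [
    "ShapeParams",
    "ShapeIntervals",
    "NoiseSpec",
    "DesignMatrix",
    "response_shape",
    "generate_shape_library",
    "shape_basis",
    "estimate_tau_and_heartbeat",
    "spectral_peaks",
    "build_design_matrix",
    "default_tau_grid",
    "shape_time_grid",
    "save_design_matrix",
    "load_design_matrix",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ShapeParams:
    """Parameters of the piecewise response-shape model r(t).

    alpha1..alpha6 are segment durations in seconds: latency, initial-dip
    duration, rise duration, plateau duration, decay duration, undershoot
    duration.  alpha7 and alpha8 are the dimensionless depths (in [0, 1]) of
    the initial dip and of the post-stimulus undershoot.

    The curve is continuous provided a nonzero depth comes with a nonzero
    duration for its segment (alpha7 > 0 needs alpha2 > 0; alpha8 > 0 needs
    alpha6 > 0); with a zero-duration segment the corresponding depth is
    simply skipped, leaving a step.
    """

    alpha1: float = 0.0
    alpha2: float = 0.0
    alpha3: float = 0.1
    alpha4: float = 0.0
    alpha5: float = 0.1
    alpha6: float = 0.0
    alpha7: float = 0.0
    alpha8: float = 0.0

    def __post_init__(self) -> None:
        durations = (self.alpha1, self.alpha2, self.alpha3,
                     self.alpha4, self.alpha5, self.alpha6)
        if any(d < 0 for d in durations):
            raise ValueError("segment durations alpha1..alpha6 must be >= 0")
        if not (0.0 <= self.alpha7 <= 1.0 and 0.0 <= self.alpha8 <= 1.0):
            raise ValueError("depths alpha7, alpha8 must lie in [0, 1]")

    @property
    def support_end(self) -> float:
        """Time after which r(t) is identically zero."""
        return (self.alpha1 + self.alpha2 + self.alpha3
                + self.alpha4 + self.alpha5 + self.alpha6)

    def as_tuple(self) -> tuple[float, ...]:
        return (self.alpha1, self.alpha2, self.alpha3, self.alpha4,
                self.alpha5, self.alpha6, self.alpha7, self.alpha8)


@dataclass(frozen=True)
class ShapeIntervals:
    """Per-parameter (min, max, n_steps) sweep ranges for the shape family.

    The library enumerates the Cartesian product of per-parameter grids; with
    ``n_steps == 1`` the midpoint of the interval is used.
    """

    alpha1: tuple[float, float, int] = (0.0, 0.1, 3)
    alpha2: tuple[float, float, int] = (0.0, 0.0, 1)
    alpha3: tuple[float, float, int] = (0.05, 0.3, 3)
    alpha4: tuple[float, float, int] = (0.0, 0.4, 3)
    alpha5: tuple[float, float, int] = (0.05, 0.3, 3)
    alpha6: tuple[float, float, int] = (0.1, 0.3, 2)
    alpha7: tuple[float, float, int] = (0.0, 0.0, 1)
    alpha8: tuple[float, float, int] = (0.0, 0.3, 3)
    cap: int = 100_000

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "alpha3", "alpha4",
                     "alpha5", "alpha6", "alpha7", "alpha8"):
            lo, hi, n = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: min {lo} exceeds max {hi}")
            if n < 1:
                raise ValueError(f"{name}: n_steps must be >= 1")

    def grids(self) -> list[np.ndarray]:
        out = []
        for name in ("alpha1", "alpha2", "alpha3", "alpha4",
                     "alpha5", "alpha6", "alpha7", "alpha8"):
            lo, hi, n = getattr(self, name)
            out.append(np.array([(lo + hi) / 2.0]) if n == 1
                       else np.linspace(lo, hi, n))
        return out

    @property
    def grid_size(self) -> int:
        return int(np.prod([g.size for g in self.grids()]))


@dataclass(frozen=True)
class NoiseSpec:
    """Noise-regressor specification for the design matrix.

    ``oscillation_freqs`` lists the oscillatory components in Hz; the first
    entry is treated as the heartbeat and receives ``n_harmonics`` harmonics,
    the remaining entries one sine/cosine pair each.
    """

    include_exponential: bool = True
    tau: float = 1.0
    oscillation_freqs: tuple[float, ...] = ()
    n_harmonics: int = 2

    def __post_init__(self) -> None:
        if self.include_exponential and self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if any(f <= 0 for f in self.oscillation_freqs):
            raise ValueError("oscillation frequencies must be positive")

    def frequency_harmonics(self) -> list[tuple[float, int]]:
        """(fundamental, harmonic) pairs in design-matrix column order."""
        pairs: list[tuple[float, int]] = []
        for i, f in enumerate(self.oscillation_freqs):
            nh = self.n_harmonics if i == 0 else 1
            pairs.extend((f, h) for h in range(1, nh + 1))
        return pairs


@dataclass
class DesignMatrix:
    """Time x regressor matrix with its constant/noise/signal partition."""

    X: np.ndarray
    labels: list[str]
    constant_idx: np.ndarray
    noise_idx: np.ndarray
    signal_idx: np.ndarray
    t_grid: np.ndarray
    sampling_rate: float
    onset_frame: int

    def __post_init__(self) -> None:
        p = self.X.shape[1]
        covered = np.sort(np.concatenate(
            [self.constant_idx, self.noise_idx, self.signal_idx]))
        if not np.array_equal(covered, np.arange(p)):
            raise ValueError("partition must disjointly cover all columns")
        if len(self.labels) != p:
            raise ValueError("one label per column required")
        if self.constant_idx.size != 1:
            raise ValueError("exactly one constant column required")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("design matrix contains non-finite entries")

    @property
    def n_frames(self) -> int:
        return self.X.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.X.shape[1]

    def heartbeat_columns(self, n_harmonics_only: bool = False) -> list[tuple[int, int]]:
        """(sin_idx, cos_idx) pairs of the heartbeat regressors, by harmonic."""
        pairs = []
        for h in itertools.count(1):
            try:
                si = self.labels.index(f"heart_sin_h{h}")
                ci = self.labels.index(f"heart_cos_h{h}")
            except ValueError:
                break
            pairs.append((si, ci))
        return pairs


def save_design_matrix(dm: DesignMatrix, basepath) -> None:
    """Persist a design matrix as <base>.tsv (columns) + <base>.json (provenance)."""
    import json
    from pathlib import Path

    base = Path(basepath)
    header = "\t".join(["time_s"] + dm.labels)
    body = np.column_stack([dm.t_grid, dm.X])
    np.savetxt(base.with_suffix(".tsv"), body, delimiter="\t",
               header=header, comments="", fmt="%.12g")
    meta = {
        "labels": dm.labels,
        "constant_idx": dm.constant_idx.tolist(),
        "noise_idx": dm.noise_idx.tolist(),
        "signal_idx": dm.signal_idx.tolist(),
        "sampling_rate": dm.sampling_rate,
        "onset_frame": dm.onset_frame,
        "n_frames": int(dm.n_frames),
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_design_matrix(basepath) -> DesignMatrix:
    """Inverse of :func:`save_design_matrix`."""
    import json
    from pathlib import Path

    base = Path(basepath)
    meta = json.loads(base.with_suffix(".json").read_text())
    body = np.loadtxt(base.with_suffix(".tsv"), delimiter="\t", skiprows=1)
    return DesignMatrix(
        X=body[:, 1:],
        labels=list(meta["labels"]),
        constant_idx=np.array(meta["constant_idx"]),
        noise_idx=np.array(meta["noise_idx"]),
        signal_idx=np.array(meta["signal_idx"]),
        t_grid=body[:, 0],
        sampling_rate=float(meta["sampling_rate"]),
        onset_frame=int(meta["onset_frame"]),
    )


def response_shape(t_grid: np.ndarray, p: ShapeParams) -> np.ndarray:
    """Evaluate the piecewise half-cosine response model on ``t_grid`` (s).

    With ``s = t - alpha1`` the curve is 0 for ``s <= 0``; dips to ``-alpha7``
    over ``(0, alpha2]``; rises from ``-alpha7`` to 1 over the next ``alpha3``;
    stays at 1 for ``alpha4``; falls from 1 to ``-alpha8`` over ``alpha5``;
    recovers from ``-alpha8`` to 0 over ``alpha6``; and is 0 afterwards.
    Each transition is a half-cosine, so the curve is continuous everywhere.
    Zero-duration segments are skipped (their half-open interval is empty).
    """
    t = np.asarray(t_grid, dtype=np.float64)
    s = t - p.alpha1
    r = np.zeros_like(s)
    a2, a3, a4, a5, a6 = p.alpha2, p.alpha3, p.alpha4, p.alpha5, p.alpha6
    a7, a8 = p.alpha7, p.alpha8
    e1, e2, e3, e4, e5 = (a2, a2 + a3, a2 + a3 + a4,
                          a2 + a3 + a4 + a5, a2 + a3 + a4 + a5 + a6)

    if a2 > 0:
        m = (s > 0) & (s <= e1)
        r[m] = (a7 / 2.0) * (np.cos(np.pi * s[m] / a2) - 1.0)
    if a3 > 0:
        m = (s > e1) & (s <= e2)
        u = s[m] - e1
        r[m] = (1 - a7) / 2.0 - (1 + a7) / 2.0 * np.cos(np.pi * u / a3)
    if a4 > 0:
        m = (s > e2) & (s <= e3)
        r[m] = 1.0
    if a5 > 0:
        m = (s > e3) & (s <= e4)
        u = s[m] - e3
        r[m] = (1 - a8) / 2.0 + (1 + a8) / 2.0 * np.cos(np.pi * u / a5)
    if a6 > 0:
        m = (s > e4) & (s <= e5)
        u = s[m] - e4
        r[m] = -(a8 / 2.0) * (1.0 + np.cos(np.pi * u / a6))
    return r


def generate_shape_library(
    intervals: ShapeIntervals, t_grid: np.ndarray
) -> np.ndarray:
    """Evaluate every parameter combination of the sweep on ``t_grid``.

    Rows follow the lexicographic order of the per-parameter grids
    (alpha1 slowest).  All-zero rows (degenerate shapes with no support on
    the grid) are dropped with a log message.
    """
    n = intervals.grid_size
    if n > intervals.cap:
        raise ValueError(
            f"shape library would contain {n} shapes, exceeding the cap of "
            f"{intervals.cap}; narrow the intervals or raise the cap"
        )
    t = np.asarray(t_grid, dtype=np.float64)
    rows = np.empty((n, t.size))
    for i, combo in enumerate(itertools.product(*intervals.grids())):
        rows[i] = response_shape(t, ShapeParams(*combo))
    nonzero = np.any(rows != 0.0, axis=1)
    dropped = int(n - nonzero.sum())
    if dropped:
        log.info("dropped %d degenerate all-zero shapes from the library", dropped)
    lib = rows[nonzero]
    if lib.shape[0] == 0:
        raise ValueError("all swept shapes are degenerate (zero on the grid)")
    return lib


def shape_basis(
    library: np.ndarray, L: int | None = None,
    center: bool = False, energy: float = 0.99,
) -> np.ndarray:
    """First L principal directions of the shape library, as a T x L matrix.

    The decomposition is an uncentered SVD by default so that the constant
    component of the shapes stays in the signal block rather than leaking
    into the baseline coefficient; ``center=True`` switches to conventional
    mean-centered PCA.  If ``L`` is None, the smallest L capturing at least
    ``energy`` of the library's (squared) singular-value energy is used.
    Columns are orthonormal, ordered by decreasing singular value, with the
    sign fixed so each column's largest-magnitude entry is positive.
    """
    lib = np.asarray(library, dtype=np.float64)
    if lib.ndim != 2:
        raise ValueError("library must be a 2D (n_shapes x T) matrix")
    work = lib - lib.mean(axis=0) if center else lib
    _, sv, vt = np.linalg.svd(work, full_matrices=False)
    max_l = int(np.sum(sv > sv[0] * 1e-12)) if sv.size else 0
    if L is None:
        cum = np.cumsum(sv**2) / np.sum(sv**2)
        L = int(np.searchsorted(cum, energy) + 1)
    if not (1 <= L <= min(lib.shape)):
        raise ValueError(
            f"L must lie in [1, {min(lib.shape)}]; got {L}"
        )
    if L > max_l:
        raise ValueError(
            f"library has numerical rank {max_l}; cannot extract L={L} components"
        )
    basis = vt[:L].T.copy()
    for j in range(L):
        k = np.argmax(np.abs(basis[:, j]))
        if basis[k, j] < 0:
            basis[:, j] = -basis[:, j]
    return basis


def shape_time_grid(
    n_frames: int, sampling_rate: float, onset_frame: int
) -> np.ndarray:
    """Time grid (s) relative to stimulus onset for building shape regressors.

    Negative entries (pre-stimulus frames) evaluate to 0 under
    :func:`response_shape` for any latency >= 0, so shape regressors built on
    this grid vanish before the onset frame.
    """
    return (np.arange(n_frames) - onset_frame) / sampling_rate


def default_tau_grid(trial_duration: float, n: int = 50) -> np.ndarray:
    """Log-spaced tau candidates spanning 0.1x to 10x the trial duration."""
    return np.geomspace(0.1 * trial_duration, 10.0 * trial_duration, n)


def _exp_fit_sse(
    y: np.ndarray, t: np.ndarray, tau: float, f_sin: float | None = None
) -> tuple[float, np.ndarray]:
    """SSE of the least-squares fit of ``c0 + c1*exp(-t/tau)`` to y.

    With ``f_sin`` given, a sine/cosine pair at that frequency is included in
    the fit (but not removed from the returned residual's definition — the
    residual is y minus the constant+exponential part only, so the
    oscillation remains visible to the periodogram).
    """
    cols = [np.ones_like(t), np.exp(-t / tau)]
    if f_sin is not None:
        w = 2.0 * np.pi * f_sin
        cols += [np.sin(w * t), np.cos(w * t)]
    X = np.column_stack(cols)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    full_resid = y - X @ coef
    exp_removed = y - X[:, :2] @ coef[:2]
    return float(full_resid @ full_resid), exp_removed


def estimate_tau_and_heartbeat(
    blank_mean_timecourse: np.ndarray,
    sampling_rate: float,
    tau_grid: np.ndarray | None = None,
    heart_band: tuple[float, float] = (1.0, 15.0),
) -> tuple[float, float]:
    """Estimate the bleaching time constant and heartbeat frequency.

    ``tau`` is selected by grid search: the candidate minimising the residual
    sum of squares of a ``constant + exp(-t/tau)`` fit to the spatially
    averaged blank timecourse.  The heartbeat frequency is the location of
    the maximum periodogram ordinate of the exponential-removed residual
    within ``heart_band``; ties break toward the lower frequency.  Because a
    strong heartbeat biases the plain exponential fit, the two estimates are
    refined jointly: a second grid search re-fits the exponential with a
    sine/cosine pair at the detected frequency included, and the frequency is
    then re-read from the refined residual.

    Raises ``ValueError`` when the band is empty after Nyquist clipping or
    when no oscillatory power is present (e.g. a constant timecourse).
    """
    y = np.asarray(blank_mean_timecourse, dtype=np.float64)
    if y.size < 16:
        raise ValueError("timecourse too short (need >= 16 samples)")
    t = np.arange(y.size) / sampling_rate
    if tau_grid is None:
        tau_grid = default_tau_grid(y.size / sampling_rate)

    lo, hi = heart_band
    hi = min(hi, sampling_rate / 2.0)

    def _tau_search(f_sin: float | None) -> tuple[float, np.ndarray]:
        sses = np.empty(len(tau_grid))
        resids = []
        for i, tau in enumerate(tau_grid):
            sses[i], r = _exp_fit_sse(y, t, float(tau), f_sin=f_sin)
            resids.append(r)
        best = int(np.argmin(sses))
        return float(tau_grid[best]), resids[best]

    def _peak_freq(resid: np.ndarray) -> float:
        # flat residual (constant or purely exponential input): nothing to find
        if np.std(resid) <= 1e-12 * max(1.0, float(np.max(np.abs(y)))):
            raise ValueError(
                "no oscillation found: timecourse has no residual variance "
                "after removing the constant and exponential components"
            )
        freqs, pxx = _sig.periodogram(resid, fs=sampling_rate)
        in_band = (freqs >= lo) & (freqs <= hi) & (freqs > 0)
        if not np.any(in_band):
            raise ValueError(
                f"heartbeat band ({lo}, {hi}) Hz contains no spectral ordinate"
            )
        band_p = pxx[in_band]
        band_f = freqs[in_band]
        scale = float(resid @ resid)
        if scale <= 0 or band_p.max() <= 1e-12 * max(scale, 1e-300):
            raise ValueError(
                "no oscillation found: periodogram is flat/zero in the heart band"
            )
        # argmax returns the first (lowest-frequency) maximum — the tie-break
        return float(band_f[int(np.argmax(band_p))])

    tau_hat, resid = _tau_search(None)
    f_heart = _peak_freq(resid)
    tau_hat, resid = _tau_search(f_heart)
    f_heart = _peak_freq(resid)
    return tau_hat, f_heart


def spectral_peaks(
    blank_mean_timecourse: np.ndarray,
    sampling_rate: float,
    z_threshold: float = 8.0,
    exclude_bands: list[tuple[float, float]] | None = None,
) -> list[float]:
    """Detect noise-related oscillation frequencies in a blank timecourse.

    Local maxima of the amplitude spectrum whose height exceeds
    ``median + z_threshold * MAD`` of all local-maximum heights are returned,
    excluding DC, the listed frequency bands, and any frequency within one
    resolution bin (fs/T) of an already-accepted stronger peak.  Sorted by
    descending amplitude; may be empty.
    """
    y = np.asarray(blank_mean_timecourse, dtype=np.float64)
    y = y - y.mean()
    amp = np.abs(np.fft.rfft(y))
    freqs = np.fft.rfftfreq(y.size, d=1.0 / sampling_rate)
    bin_width = sampling_rate / y.size

    peak_idx, _ = _sig.find_peaks(amp)
    peak_idx = peak_idx[freqs[peak_idx] > 0]
    if peak_idx.size == 0:
        return []
    heights = amp[peak_idx]
    med = np.median(heights)
    mad = np.median(np.abs(heights - med))
    thresh = med + z_threshold * mad
    candidates = peak_idx[heights > thresh]
    if exclude_bands:
        for lo, hi in exclude_bands:
            candidates = candidates[
                (freqs[candidates] < lo) | (freqs[candidates] > hi)
            ]
    # strongest first; suppress near-duplicates within one resolution bin
    order = np.argsort(amp[candidates])[::-1]
    accepted: list[float] = []
    for i in candidates[order]:
        f = float(freqs[i])
        if all(abs(f - g) > bin_width for g in accepted):
            accepted.append(f)
    return accepted


def build_design_matrix(
    n_frames: int,
    sampling_rate: float,
    onset_frame: int,
    noise: NoiseSpec | None = None,
    shape_basis_matrix: np.ndarray | None = None,
) -> DesignMatrix:
    """Assemble the full design matrix [constant | noise | signal].

    Column order is fixed: the all-ones constant; the bleaching exponential
    (if enabled); sine/cosine pairs per oscillation frequency and harmonic
    (heartbeat first); then the L shape-basis columns.  Construction fails on
    any harmonic at or above Nyquist and on rank deficiency, reporting the
    condition number.
    """
    t = np.arange(n_frames) / sampling_rate
    cols: list[np.ndarray] = [np.ones(n_frames)]
    labels: list[str] = ["constant"]
    noise_labels: list[str] = []

    if noise is not None:
        if noise.include_exponential:
            cols.append(np.exp(-t / noise.tau))
            labels.append("bleach_exp")
            noise_labels.append("bleach_exp")
        nyq = sampling_rate / 2.0
        for i, (f, h) in enumerate(noise.frequency_harmonics()):
            fh = f * h
            if fh >= nyq:
                raise ValueError(
                    f"harmonic {h} of {f} Hz is {fh} Hz, at or above the "
                    f"Nyquist frequency {nyq} Hz"
                )
            prefix = "heart" if f == noise.oscillation_freqs[0] else f"osc{f:g}Hz"
            w = 2.0 * np.pi * fh
            cols.append(np.sin(w * t))
            cols.append(np.cos(w * t))
            labels.extend([f"{prefix}_sin_h{h}", f"{prefix}_cos_h{h}"])
            noise_labels.extend([f"{prefix}_sin_h{h}", f"{prefix}_cos_h{h}"])

    n_signal = 0
    if shape_basis_matrix is not None:
        B = np.asarray(shape_basis_matrix, dtype=np.float64)
        if B.shape[0] != n_frames:
            raise ValueError(
                f"shape basis has {B.shape[0]} rows; expected T={n_frames}"
            )
        for j in range(B.shape[1]):
            cols.append(B[:, j])
            labels.append(f"shape_pc{j + 1}")
        n_signal = B.shape[1]

    X = np.column_stack(cols)
    p = X.shape[1]
    sv = np.linalg.svd(X, compute_uv=False)
    if sv[-1] <= sv[0] * np.finfo(float).eps * max(X.shape):
        # identify offending (linearly dependent) columns by QR pivoting
        from scipy.linalg import qr as _qr
        _, R, piv = _qr(X, pivoting=True, mode="economic")
        rank = int(np.sum(np.abs(np.diag(R)) > np.abs(R[0, 0]) * 1e-10))
        bad = [labels[i] for i in piv[rank:]]
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {p} columns; "
            f"condition number {sv[0] / max(sv[-1], 1e-300):.3g}); "
            f"dependent columns: {bad}"
        )
    n_noise = len(noise_labels)
    return DesignMatrix(
        X=X,
        labels=labels,
        constant_idx=np.array([0]),
        noise_idx=np.arange(1, 1 + n_noise),
        signal_idx=np.arange(1 + n_noise, 1 + n_noise + n_signal),
        t_grid=t,
        sampling_rate=sampling_rate,
        onset_frame=onset_frame,
    )
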