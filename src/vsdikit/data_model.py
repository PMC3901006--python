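"""Core data types, NIfTI-1 I/O, trial-file naming and the session condition table.

Axis convention (used everywhere in the package): in memory a trial stack is a
float array indexed ``(row, column, frame)`` of shape ``H x W x T``.  On disk it
is a 4D NIfTI-1 volume with axes ``(X=W, Y=H, Z=1, T)`` — i.e. the first NIfTI
axis runs along image columns — with ``pixdim[4]`` set to the frame period in
seconds and 32-bit float voxels.

Frame indexing is 0-based throughout.  ``onset_frame`` is the index of the
first post-stimulus frame, so the pre-stimulus ("frames 0") window is the
half-open frame range ``[0, onset_frame)``.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "TrialMeta",
    "TrialStack",
    "SessionIndex",
    "write_stack",
    "read_stack",
    "make_trial_filename",
    "parse_trial_filename",
    "build_condition_table",
    "bin_stack",
    "BLANK_CONDITION",
]

#: Condition code reserved for blank (no-stimulus) trials.
BLANK_CONDITION = 0

_FILENAME_RE = re.compile(
    r"^(?P<date>\d{8})_exp(?P<exp>\d{2,})_trial(?P<trial>\d{4,})_cond(?P<cond>\d{2,})"
    r"\.nii(?P<gz>\.gz)?$"
)


@dataclass(frozen=True)
class TrialMeta:
    """Identity of one acquired trial within a session.

    ``condition_code`` 0 is reserved for blank trials (no stimulus); any
    positive code is an opaque stimulus-condition label.
    """

    session_date: _dt.date
    experiment_number: int
    trial_number: int
    condition_code: int

    def __post_init__(self) -> None:
        if self.experiment_number < 1:
            raise ValueError("experiment_number must be a positive integer")
        if self.trial_number < 1:
            raise ValueError("trial_number must be a positive integer")
        if self.condition_code < 0:
            raise ValueError("condition_code must be non-negative")

    @property
    def is_blank(self) -> bool:
        return self.condition_code == BLANK_CONDITION


@dataclass
class TrialStack:
    """One trial's 2D+t fluorescence movie with acquisition metadata.

    Parameters
    ----------
    data
        Fluorescence intensities (arbitrary units), shape ``(H, W, T)``.
    sampling_rate
        Acquisition frequency in Hz.
    onset_frame
        0-based index of the first post-stimulus frame; frames before it form
        the pre-stimulus baseline window.
    meta
        Trial identity (:class:`TrialMeta`).
    """

    data: np.ndarray
    sampling_rate: float
    onset_frame: int
    meta: TrialMeta

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3D (H, W, T); got {self.data.ndim}D")
        h, w, t = self.data.shape
        if t < 2 or h < 1 or w < 1:
            raise ValueError(f"stack must be at least 1x1x2; got {self.data.shape}")
        if not (1 <= self.onset_frame < t):
            raise ValueError(
                f"onset_frame must lie in [1, T); got {self.onset_frame} with T={t}"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds, starting at 0."""
        return np.arange(self.n_frames) / self.sampling_rate


@dataclass
class SessionIndex:
    """Registry of all trials of one session.

    All records must share identical spatial/temporal dimensions, sampling
    rate and onset frame — the preconditions for blank averaging and for a
    design matrix shared across trials.
    """

    records: pd.DataFrame = field(repr=False)

    COLUMNS = (
        "trial_id",
        "filename",
        "condition",
        "onset_frame",
        "n_frames",
        "height",
        "width",
        "sampling_rate_hz",
    )

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"condition table missing columns: {sorted(missing)}")
        dup = self.records["trial_id"].duplicated()
        if dup.any():
            raise ValueError(
                "duplicate (experiment, trial) identifiers: "
                + ", ".join(self.records.loc[dup, "trial_id"])
            )
        for col in ("onset_frame", "n_frames", "height", "width", "sampling_rate_hz"):
            if self.records[col].nunique() != 1:
                offenders = self.records.loc[
                    self.records[col] != self.records[col].iloc[0], "filename"
                ]
                raise ValueError(
                    f"heterogeneous '{col}' across trials; offending files: "
                    + ", ".join(offenders)
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def blanks(self) -> pd.DataFrame:
        return self.records[self.records["condition"] == BLANK_CONDITION]

    @property
    def stimulated(self) -> pd.DataFrame:
        return self.records[self.records["condition"] != BLANK_CONDITION]

    @property
    def conditions(self) -> list[int]:
        """Sorted non-blank condition codes present in the session."""
        return sorted(c for c in self.records["condition"].unique() if c != 0)

    def paths(self, condition: int | None = None) -> list[Path]:
        rec = self.records if condition is None else self.records[
            self.records["condition"] == condition
        ]
        return [Path(f) for f in rec["filename"]]


def make_trial_filename(meta: TrialMeta, compress: bool = True) -> str:
    """Encode trial metadata in a sortable filename.

    Format: ``<YYYYMMDD>_exp<EE>_trial<TTTT>_cond<CC>.nii[.gz]``.
    """
    ext = ".nii.gz" if compress else ".nii"
    return (
        f"{meta.session_date:%Y%m%d}_exp{meta.experiment_number:02d}"
        f"_trial{meta.trial_number:04d}_cond{meta.condition_code:02d}{ext}"
    )


def parse_trial_filename(name: str) -> TrialMeta:
    """Inverse of :func:`make_trial_filename`; raises on non-conforming names."""
    m = _FILENAME_RE.match(Path(name).name)
    if m is None:
        raise ValueError(
            f"filename {name!r} does not follow the "
            "<YYYYMMDD>_exp<EE>_trial<TTTT>_cond<CC>.nii[.gz] convention"
        )
    date = _dt.datetime.strptime(m.group("date"), "%Y%m%d").date()
    return TrialMeta(
        session_date=date,
        experiment_number=int(m.group("exp")),
        trial_number=int(m.group("trial")),
        condition_code=int(m.group("cond")),
    )


def write_stack(stack: TrialStack, path: str | Path) -> Path:
    """Write a trial as a 4D NIfTI-1 file ``(W, H, 1, T)``, float32 voxels.

    The frame period ``1/sampling_rate`` (seconds) is stored in ``pixdim[4]``.
    The filename (taken from ``path`` if it conforms, else generated from the
    stack's metadata into the directory ``path``) encodes the trial identity.
    """
    path = Path(path)
    if path.is_dir():
        path = path / make_trial_filename(stack.meta)
    else:
        parse_trial_filename(path.name)  # validate early
    # (row, col, frame) -> NIfTI (X=col, Y=row, Z=1, T)
    vol = np.transpose(stack.data, (1, 0, 2))[:, :, np.newaxis, :].astype(np.float32)
    img = nib.Nifti1Image(vol, affine=np.eye(4))
    img.header.set_xyzt_units("mm", "sec")
    zooms = list(img.header.get_zooms())
    zooms[3] = 1.0 / stack.sampling_rate
    img.header.set_zooms(zooms)
    # onset frame travels in the header's toffset field (seconds)
    img.header["toffset"] = stack.onset_frame / stack.sampling_rate
    nib.save(img, str(path))
    return path


def read_stack(path: str | Path) -> TrialStack:
    """Read a trial written by :func:`write_stack`.

    Metadata is recovered from the filename; the sampling rate and onset
    frame from the NIfTI header.
    """
    path = Path(path)
    meta = parse_trial_filename(path.name)
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(
            f"{path.name}: expected a 4D volume (X, Y, 1, T); file is {img.ndim}D"
        )
    vol = np.asanyarray(img.dataobj)
    if vol.shape[2] != 1:
        raise ValueError(
            f"{path.name}: third (Z) axis must be singleton; got size {vol.shape[2]}"
        )
    dt = float(img.header.get_zooms()[3])
    if dt <= 0:
        raise ValueError(f"{path.name}: non-positive frame period in header")
    sampling_rate = 1.0 / dt
    onset_frame = int(round(float(img.header["toffset"]) * sampling_rate))
    data = np.transpose(vol[:, :, 0, :], (1, 0, 2)).astype(np.float64)
    return TrialStack(
        data=data, sampling_rate=sampling_rate, onset_frame=onset_frame, meta=meta
    )


def build_condition_table(
    source: str | Path | Sequence[str | Path],
    table_path: str | Path | None = None,
) -> SessionIndex:
    """Index all trial files of a session and write the condition table.

    ``source`` is a directory (scanned for ``*.nii[.gz]``) or an explicit list
    of paths.  The table has one row per trial, sorted by (experiment, trial),
    and is written as tab-separated UTF-8 text with a header line.
    """
    if isinstance(source, (str, Path)) and Path(source).is_dir():
        paths = sorted(
            p for p in Path(source).iterdir() if _FILENAME_RE.match(p.name)
        )
    else:
        paths = [Path(p) for p in source]  # type: ignore[union-attr]
    if not paths:
        raise ValueError("no parsable trial files found")

    rows = []
    for p in paths:
        meta = parse_trial_filename(p.name)
        img = nib.load(str(p))
        if img.ndim != 4 or img.shape[2] != 1:
            raise ValueError(f"{p.name}: not a 4D (X, Y, 1, T) trial volume")
        w, h, _, t = img.shape
        dt = float(img.header.get_zooms()[3])
        fs = 1.0 / dt
        onset = int(round(float(img.header["toffset"]) * fs))
        rows.append(
            {
                "trial_id": f"exp{meta.experiment_number:02d}"
                f"_trial{meta.trial_number:04d}",
                "filename": str(p),
                "condition": meta.condition_code,
                "onset_frame": onset,
                "n_frames": t,
                "height": h,
                "width": w,
                "sampling_rate_hz": fs,
                "_sort": (meta.experiment_number, meta.trial_number),
            }
        )
    df = pd.DataFrame(rows).sort_values("_sort").drop(columns="_sort")
    df = df.reset_index(drop=True)
    index = SessionIndex(records=df)
    if table_path is not None:
        df.to_csv(table_path, sep="\t", index=False)
    return index


def read_condition_table(table_path: str | Path) -> SessionIndex:
    """Load a previously written condition table."""
    df = pd.read_csv(table_path, sep="\t")
    return SessionIndex(records=df)


def bin_stack(
    stack: TrialStack, spatial_factor: int = 1, temporal_factor: int = 1
) -> TrialStack:
    """Average the stack over non-overlapping blocks.

    Each output value is the arithmetic mean of its ``s x s x k`` source
    block; trailing rows/columns/frames that do not fill a block are dropped.
    The sampling rate is divided by ``k`` and the onset frame mapped to
    ``onset // k``.
    """
    s, k = int(spatial_factor), int(temporal_factor)
    if s < 1 or k < 1:
        raise ValueError("binning factors must be positive integers")
    h, w, t = stack.shape
    if s > h or s > w or k > t:
        raise ValueError(
            f"binning factor exceeds a dimension: factors ({s}, {s}, {k}) "
            f"vs shape {stack.shape}"
        )
    hb, wb, tb = h // s, w // s, t // k
    d = stack.data[: hb * s, : wb * s, : tb * k]
    d = d.reshape(hb, s, wb, s, tb, k).mean(axis=(1, 3, 5))
    return TrialStack(
        data=d,
        sampling_rate=stack.sampling_rate / k,
        onset_frame=stack.onset_frame // k,
        meta=stack.meta,
    )
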