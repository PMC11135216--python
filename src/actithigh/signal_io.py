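"""Reading, writing, cropping and resampling accelerometer recordings.

Conventions
-----------
* Acceleration is in units of g. With the device strapped to the lateral
  thigh, the x axis points toward the floor while standing, so quiet standing
  reads roughly (1, 0, 0) g.
* Time is in seconds, zero-based from the start of the recording; all
  intervals are half-open ``[start, end)`` so that complementary crops
  partition a recording exactly.
* Signal CSV dialect: header ``time_s,ax_g,ay_g,az_g``, one sample per row,
  decimal point, UTF-8. Lines starting with ``#`` before the header are
  treated as comments (used to embed run configuration).
* Annotation CSV dialect: header ``start_s,end_s,label`` with fine-class
  labels from :mod:`actithigh.taxonomy`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError
from .taxonomy import FINE_CLASSES

SIGNAL_HEADER = ("time_s", "ax_g", "ay_g", "az_g")
ANNOTATION_HEADER = ("start_s", "end_s", "label")

AXES = ("x", "y", "z")


@dataclass
class Recording:
    """A uniformly sampled triaxial acceleration trace.

    Attributes
    ----------
    t : ndarray, shape (n,)
        Sample times in seconds, strictly increasing.
    a : ndarray, shape (n, 3)
        Acceleration in g, columns x, y, z.
    fs : float
        Sampling frequency in Hz.
    """

    t: np.ndarray
    a: np.ndarray
    fs: float = 100.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.a.ndim != 2 or self.a.shape[1] != 3:
            raise DataError(f"acceleration must be (n, 3); got {self.a.shape}")
        if len(self.t) != len(self.a):
            raise DataError("time and acceleration lengths differ")
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise DataError("sample times must be strictly increasing")
        if not np.all(np.isfinite(self.a)) or not np.all(np.isfinite(self.t)):
            raise DataError("recording contains non-finite values")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return 0.0 if len(self.t) == 0 else float(self.t[-1] - self.t[0])

    def is_uniform(self, rel_tol: float = 1e-6) -> bool:
        if len(self.t) < 2:
            return True
        return bool(np.max(np.abs(np.diff(self.t) * self.fs - 1.0)) <= rel_tol * self.fs + 1e-9)

    def magnitude(self) -> np.ndarray:
        """Euclidean norm of the acceleration vector per sample, in g."""
        return np.linalg.norm(self.a, axis=1)


@dataclass
class AnnotationTrack:
    """Ground-truth behavior intervals: (start_s, end_s, label), half-open."""

    intervals: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals)
        for start, end, label in ivs:
            if not start < end:
                raise DataError(f"annotation interval has start >= end: ({start}, {end})")
            if label not in FINE_CLASSES:
                raise DataError(f"unknown behavior label {label!r}")
        for (s0, e0, _), (s1, _, _) in zip(ivs, ivs[1:]):
            if s1 < e0 - 1e-9:
                raise DataError(f"annotation intervals overlap near t={s1:g} s")
        self.intervals = ivs

    def clip(self, start_s: float, end_s: float, rebase: bool = True) -> "AnnotationTrack":
        """Restrict to [start_s, end_s); optionally shift times to start at 0."""
        off = start_s if rebase else 0.0
        out = []
        for s, e, lab in self.intervals:
            s2, e2 = max(s, start_s), min(e, end_s)
            if s2 < e2:
                out.append((s2 - off, e2 - off, lab))
        return AnnotationTrack(out)

    def shift(self, offset_s: float) -> "AnnotationTrack":
        return AnnotationTrack([(s + offset_s, e + offset_s, lab) for s, e, lab in self.intervals])


def _read_table(path: str | Path, header: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except pd.errors.ParserError as exc:
        raise DataError(f"{path.name}: malformed CSV: {exc}") from exc
    if tuple(df.columns) != header:
        raise DataError(
            f"{path.name}: header {tuple(df.columns)} does not match required {header}"
        )
    return df


def read_recording(path: str | Path) -> Recording:
    """Read a signal CSV and infer the sampling frequency.

    fs is inferred from the median inter-sample gap, which is robust to a few
    jittered timestamps from real loggers.

    Raises
    ------
    DataError
        On malformed rows (naming the offending line), non-finite values, or
        non-monotone time.
    """
    path = Path(path)
    df = _read_table(path, SIGNAL_HEADER)
    values = df.to_numpy()
    bad = ~np.isfinite(values).all(axis=1)
    if bad.any():
        # +2: 1-based line numbering plus the header row
        line = int(np.flatnonzero(bad)[0]) + 2
        raise DataError(f"{path.name}: malformed or non-finite row at line {line}")
    t = values[:, 0]
    if len(t) < 2:
        raise DataError(f"{path.name}: need at least 2 samples")
    if not np.all(np.diff(t) > 0):
        raise DataError(f"{path.name}: sample times are not strictly increasing")
    fs = 1.0 / float(np.median(np.diff(t)))
    return Recording(t=t, a=values[:, 1:], fs=fs)


def write_recording(r: Recording, path: str | Path, comments: list[str] | None = None) -> None:
    """Write a signal CSV; round-trips through :func:`read_recording` to 1e-9 g."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        fh.write(",".join(SIGNAL_HEADER) + "\n")
        buf = io.StringIO()
        np.savetxt(buf, np.column_stack([r.t, r.a]), fmt="%.10f", delimiter=",")
        fh.write(buf.getvalue())


def read_annotations(path: str | Path) -> AnnotationTrack:
    df = _read_table(Path(path), ANNOTATION_HEADER)
    return AnnotationTrack(
        [(float(s), float(e), str(lab)) for s, e, lab in df.itertuples(index=False)]
    )


def write_annotations(ann: AnnotationTrack, path: str | Path, comments: list[str] | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        fh.write(",".join(ANNOTATION_HEADER) + "\n")
        for s, e, lab in ann.intervals:
            fh.write(f"{s:.6f},{e:.6f},{lab}\n")


def resample_uniform(r: Recording, fs_target: float) -> Recording:
    """Linearly interpolate onto a uniform grid at ``fs_target`` over [t0, tN]."""
    if fs_target <= 0:
        raise ValueError("fs_target must be positive")
    if len(r) < 2:
        raise DataError("need at least 2 samples to resample")
    t0, t1 = float(r.t[0]), float(r.t[-1])
    n = int(np.floor((t1 - t0) * fs_target + 1e-9)) + 1
    grid = t0 + np.arange(n) / fs_target
    a = np.column_stack([np.interp(grid, r.t, r.a[:, k]) for k in range(3)])
    return Recording(t=grid, a=a, fs=float(fs_target))


def crop(r: Recording, start_s: float, end_s: float) -> Recording:
    """Samples with ``start_s <= t < end_s`` (half-open).

    Callers clip annotation tracks separately via ``AnnotationTrack.clip``.
    """
    if not start_s < end_s:
        raise ValueError("start_s must be < end_s")
    mask = (r.t >= start_s) & (r.t < end_s)
    if not mask.any():
        raise DataError(f"crop [{start_s}, {end_s}) selects no samples")
    return Recording(t=r.t[mask], a=r.a[mask], fs=r.fs)


def detect_tap_markers(
    r: Recording,
    threshold_g: float = 2.0,
    max_gap_s: float = 0.5,
    refractory_s: float = 0.1,
) -> list[float]:
    """Detect triple-tap segment markers.

    A marker is three (or more) sharp magnitude excursions above
    ``threshold_g`` — measured after removing the 1 g gravity baseline — whose
    consecutive gaps are each at most ``max_gap_s``. Exceedances closer than
    ``refractory_s`` count as one tap. Each qualifying run collapses to a
    single marker time at its first tap.

    Returns an empty list when no triplet is found.
    """
    if len(r) == 0:
        return []
    excess = np.abs(r.magnitude() - 1.0)
    above = np.flatnonzero(excess > threshold_g)
    if len(above) == 0:
        return []
    # collapse contiguous/refractory-close exceedances into individual taps
    taps = [r.t[above[0]]]
    for idx in above[1:]:
        if r.t[idx] - taps[-1] > refractory_s:
            taps.append(r.t[idx])
    # group taps into runs with consecutive gaps <= max_gap_s
    markers: list[float] = []
    run_start = 0
    for i in range(1, len(taps) + 1):
        if i == len(taps) or taps[i] - taps[i - 1] > max_gap_s:
            if i - run_start >= 3:
                markers.append(float(taps[run_start]))
            run_start = i
    return markers
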