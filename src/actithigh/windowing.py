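"""Sliding-window segmentation and per-window feature extraction.

A recording is cut into 1-second windows that advance by 0.5 s, so
consecutive windows overlap by half. Each window gets the ground-truth label
covering the majority of its span, and a 24-dimensional feature vector:
seven time-domain statistics per axis plus the three pairwise Pearson
correlations.

Per-axis statistics (in feature-vector order): mean, sample SD (n-1
denominator), RMS, peak count, maximum, minimum, distinctive-point count.

Two of the statistics are thresholded operators rather than closed-form
moments, and both thresholds are exposed as parameters:

* ``peak count`` — number of local maxima whose topographic prominence is at
  least ``peak_prominence_g`` (default 0.1 g). An unfiltered local-maximum
  count would be dominated by sensor noise.
* ``distinctive points`` — number of samples whose absolute first difference
  exceeds ``distinct_threshold_g`` (default 0.05 g), i.e. how often the
  signal changes abruptly; monotone in movement intensity.

Pairwise correlations are defined as 0 when either axis has zero variance,
so static postures (sitting, lying) stay representable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .exceptions import DataError
from .signal_io import AXES, AnnotationTrack, Recording

DEFAULT_WINDOW_S = 1.0
DEFAULT_STEP_S = 0.5
DEFAULT_PEAK_PROMINENCE_G = 0.1
DEFAULT_DISTINCT_THRESHOLD_G = 0.05

_AXIS_STATS = ("mean", "sd", "rms", "peaks", "max", "min", "distinct")

#: Column order of the feature matrix: 7 stats for x, then y, then z,
#: then the three pairwise correlations. Length 24.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{stat}_{axis}" for axis in AXES for stat in _AXIS_STATS
) + ("corr_xy", "corr_xz", "corr_yz")


@dataclass
class Window:
    """One analysis window: ``fs`` samples starting at ``start_s``."""

    start_s: float
    samples: np.ndarray  # (n, 3) in g
    fs: float
    label: str | None = None

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


def segment(
    r: Recording, win_s: float = DEFAULT_WINDOW_S, step_s: float = DEFAULT_STEP_S
) -> list[Window]:
    """Cut a uniform recording into overlapping windows.

    Windows start at 0, step_s, 2*step_s, ... relative to the first sample;
    a trailing partial window is dropped. For N samples this yields
    ``floor((N - win) / step) + 1`` windows when N >= win, else none.
    """
    win = win_s * r.fs
    step = step_s * r.fs
    if abs(win - round(win)) > 1e-6 or abs(step - round(step)) > 1e-6:
        raise ValueError("win_s*fs and step_s*fs must be integral")
    win, step = int(round(win)), int(round(step))
    if win <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    n = len(r)
    if n < win:
        return []
    t0 = float(r.t[0])
    return [
        Window(start_s=t0 + i * step / r.fs, samples=r.a[i * step : i * step + win], fs=r.fs)
        for i in range((n - win) // step + 1)
    ]


def label_window(w: Window, ann: AnnotationTrack) -> str | None:
    """Label covering the majority of the window's time span.

    Returns None when no annotated class overlaps the window at all. Ties in
    covered duration go to the class whose contributing interval starts
    earlier.
    """
    w_start, w_end = w.start_s, w.start_s + w.duration_s
    cover: dict[str, float] = {}
    first_start: dict[str, float] = {}
    for s, e, lab in ann.intervals:
        overlap = min(e, w_end) - max(s, w_start)
        if overlap > 1e-12:
            cover[lab] = cover.get(lab, 0.0) + overlap
            first_start.setdefault(lab, s)
    if not cover:
        return None
    best = max(cover.values())
    tied = [lab for lab, v in cover.items() if v >= best - 1e-12]
    return min(tied, key=lambda lab: first_start[lab])


def extract_features(
    w: Window,
    peak_prominence_g: float = DEFAULT_PEAK_PROMINENCE_G,
    distinct_threshold_g: float = DEFAULT_DISTINCT_THRESHOLD_G,
) -> np.ndarray:
    """Compute the 24-dimensional feature vector for one window.

    Deterministic: identical samples give a bit-identical vector.
    """
    a = np.asarray(w.samples, dtype=float)
    if not np.all(np.isfinite(a)):
        raise DataError("window contains non-finite samples")
    out = np.empty(len(FEATURE_NAMES))
    k = 0
    for ax in range(3):
        x = a[:, ax]
        out[k] = x.mean()
        out[k + 1] = x.std(ddof=1) if len(x) > 1 else 0.0
        out[k + 2] = np.sqrt(np.mean(x**2))
        peaks, _ = find_peaks(x, prominence=peak_prominence_g)
        out[k + 3] = len(peaks)
        out[k + 4] = x.max()
        out[k + 5] = x.min()
        out[k + 6] = int(np.sum(np.abs(np.diff(x)) > distinct_threshold_g))
        k += 7
    for i, j in ((0, 1), (0, 2), (1, 2)):
        xi, xj = a[:, i], a[:, j]
        si, sj = xi.std(), xj.std()
        if si == 0.0 or sj == 0.0:
            out[k] = 0.0
        else:
            out[k] = float(np.corrcoef(xi, xj)[0, 1])
        k += 1
    return out


def build_dataset(
    recordings: list[tuple[Recording, AnnotationTrack]],
    win_s: float = DEFAULT_WINDOW_S,
    step_s: float = DEFAULT_STEP_S,
    peak_prominence_g: float = DEFAULT_PEAK_PROMINENCE_G,
    distinct_threshold_g: float = DEFAULT_DISTINCT_THRESHOLD_G,
) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
    """Windows from all recordings -> (feature matrix, labels, class counts).

    Rows follow recording order, then window order within each recording.
    Unlabeled windows are dropped. The per-class window counts are returned
    as a class-imbalance audit.
    """
    rows: list[np.ndarray] = []
    labels: list[str] = []
    for rec, ann in recordings:
        for w in segment(rec, win_s, step_s):
            lab = label_window(w, ann)
            if lab is None:
                continue
            rows.append(extract_features(w, peak_prominence_g, distinct_threshold_g))
            labels.append(lab)
    if not rows:
        raise DataError("no labeled windows in input recordings")
    y = np.array(labels)
    counts = {lab: int(n) for lab, n in zip(*np.unique(y, return_counts=True))}
    return np.vstack(rows), y, counts


def feature_frame(
    r: Recording,
    ann: AnnotationTrack | None = None,
    win_s: float = DEFAULT_WINDOW_S,
    step_s: float = DEFAULT_STEP_S,
    peak_prominence_g: float = DEFAULT_PEAK_PROMINENCE_G,
    distinct_threshold_g: float = DEFAULT_DISTINCT_THRESHOLD_G,
):
    """Feature table for one recording: columns ``start_s,label,<24 features>``.

    Windows with no annotation coverage get an empty label; with ``ann`` omitted
    all labels are empty (prediction-time use).
    """
    import pandas as pd

    windows = segment(r, win_s, step_s)
    data = {
        "start_s": [w.start_s for w in windows],
        "label": [
            (label_window(w, ann) or "") if ann is not None else "" for w in windows
        ],
    }
    feats = (
        np.array([extract_features(w, peak_prominence_g, distinct_threshold_g) for w in windows])
        if windows
        else np.empty((0, len(FEATURE_NAMES)))
    )
    for j, name in enumerate(FEATURE_NAMES):
        data[name] = feats[:, j]
    return pd.DataFrame(data)
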