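"""Bundled reference confusion matrices.

Four published validation-scale confusion matrices for thigh-accelerometer
behavior classification ship with the package as fixed integer tables. They
exercise the metric arithmetic (per-class F-measure, macro averaging,
merging bookkeeping) against realistic class-imbalance patterns without any
raw sensor data:

* ``crossval_11class`` — 11-class stratified 10-fold cross-validation on
  pooled training windows (within-individual evaluation; strong agreement).
* ``external_11class`` — the same 11-class model applied to sessions from
  individuals absent from training (subject-held-out; marked performance drop).
* ``external_merged_5class`` — the subject-held-out evaluation after merging
  to five coarse classes and excluding driving / wheelchair ambulation.
* ``external_threshold_5class`` — a threshold-based comparison algorithm on
  the same five-class sessions.

Entries are counts of window-level "seconds" (1 s windows stepping by 0.5 s).
"""

from __future__ import annotations

from importlib import resources

from .evaluation import ConfusionMatrix, read_confusion_csv

REFERENCE_MATRICES = (
    "crossval_11class",
    "external_11class",
    "external_merged_5class",
    "external_threshold_5class",
)


def load_reference_matrix(name: str) -> ConfusionMatrix:
    """Load one of :data:`REFERENCE_MATRICES` by name."""
    if name not in REFERENCE_MATRICES:
        raise KeyError(f"unknown reference matrix {name!r}; available: {REFERENCE_MATRICES}")
    with resources.as_file(
        resources.files("actithigh").joinpath(f"data/{name}.csv")
    ) as path:
        return read_confusion_csv(path)
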