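"""Behavior-class taxonomy and class-merging schemes.

The package classifies eleven fine-grained physical behaviors from a single
thigh-mounted triaxial accelerometer. The fine-class ordering below is fixed:
every confusion matrix, model file and report uses it, so results from
different runs line up column for column.

Coarse (merged) classes collapse behaviors that are indistinguishable or
interchangeable for many monitoring questions: sitting and lying become
``sedentary``; walking, both stair-climbing directions and postural
transitions become ``walking``; driving and wheelchair ambulation are
excluded outright because threshold-style comparison algorithms do not
implement them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Canonical fine-class order. Confusion-matrix rows/columns and classifier
#: tie-breaking follow this order everywhere.
FINE_CLASSES: tuple[str, ...] = (
    "sitting",
    "transitioning",
    "walking",
    "standing",
    "lying",
    "ascending_stairs",
    "cycling",
    "descending_stairs",
    "running",
    "driving",
    "wheelchair",
)

#: Canonical coarse-class order used after five-class merging.
MERGED_CLASSES: tuple[str, ...] = (
    "sedentary",
    "walking",
    "standing",
    "cycling",
    "running",
)

#: Pseudo-class for retained samples predicted as a class the merge scheme
#: neither maps nor keeps (possible when an 11-class model is applied before
#: merging). Counts as an error against the sample's true class.
OTHER_CLASS = "other"


def class_index(name: str) -> int:
    """Position of a fine class in the canonical order."""
    try:
        return FINE_CLASSES.index(name)
    except ValueError:
        raise KeyError(f"unknown behavior class: {name!r}") from None


@dataclass(frozen=True)
class MergeScheme:
    """A many-to-one map from fine to coarse classes plus an exclusion set.

    Samples whose *ground-truth* class is in ``excluded`` are dropped before
    evaluation. Remaining labels (truth and prediction alike) are passed
    through ``mapping``; a predicted label that is excluded and unmapped
    becomes :data:`OTHER_CLASS`.
    """

    name: str
    mapping: dict[str, str] = field(default_factory=dict)
    excluded: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        unknown = (set(self.mapping) | self.excluded) - set(FINE_CLASSES)
        if unknown:
            raise KeyError(f"unknown behavior classes in scheme: {sorted(unknown)}")
        missing = set(FINE_CLASSES) - set(self.mapping) - self.excluded
        if missing:
            raise ValueError(
                f"scheme {self.name!r} leaves fine classes unmapped: {sorted(missing)}"
            )

    def coarse_classes(self) -> tuple[str, ...]:
        """Coarse classes in canonical order (first appearance of each)."""
        if self.name == "fiveclass":
            return MERGED_CLASSES
        seen: list[str] = []
        for fine in FINE_CLASSES:
            coarse = self.mapping.get(fine)
            if coarse is not None and coarse not in seen:
                seen.append(coarse)
        return tuple(seen)

    def apply(self, label: str) -> str | None:
        """Coarse label for a fine label, or None if excluded/unmapped."""
        return self.mapping.get(label)


def identity_scheme() -> MergeScheme:
    """No-op scheme: every fine class maps to itself, nothing excluded."""
    return MergeScheme("identity", {c: c for c in FINE_CLASSES})


def five_class_scheme() -> MergeScheme:
    """The five-class comparison scheme.

    sitting+lying -> sedentary; walking, stairs and transitioning -> walking;
    standing, cycling, running map to themselves; driving and wheelchair
    ambulation are excluded.
    """
    return MergeScheme(
        "fiveclass",
        mapping={
            "sitting": "sedentary",
            "lying": "sedentary",
            "walking": "walking",
            "ascending_stairs": "walking",
            "descending_stairs": "walking",
            "transitioning": "walking",
            "standing": "standing",
            "cycling": "cycling",
            "running": "running",
        },
        excluded=frozenset({"driving", "wheelchair"}),
    )


SCHEMES = {
    "none": identity_scheme,
    "identity": identity_scheme,
    "fiveclass": five_class_scheme,
}


def get_scheme(name: str) -> MergeScheme:
    try:
        return SCHEMES[name]()
    except KeyError:
        raise KeyError(
            f"unknown merge scheme {name!r}; available: {sorted(SCHEMES)}"
        ) from None
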