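"""Synthetic thigh-accelerometer recordings with known ground truth.

The generator emulates the signal structure a thigh-worn triaxial
accelerometer sees during everyday behaviors, at the level the downstream
time-domain features can resolve:

* a posture-dependent projection of gravity onto the three axes (x toward
  the floor while standing, so quiet standing reads ~(1, 0, 0) g and seated
  postures tip gravity onto y/z);
* class-specific periodic components for gait-like behaviors (walking,
  running, stair ascent/descent, cycling), with per-bout frequency jitter
  and random phase;
* low-amplitude vibration for vehicle driving and intermittent push bursts
  for wheelchair ambulation — both seated, so their mean orientation is
  nearly identical to sitting and only the dynamics differ;
* smooth 1-3 s orientation ramps for the transitioning class;
* Gaussian white sensor noise;
* optional triple-tap start/stop markers (three sharp spikes).

Every level (bout, session, cohort) is deterministic per seed. Default
frequencies and amplitudes are package constants chosen for physiological
plausibility; they are documented in ``docs/methods.md`` and are not fit to
any particular dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signal_io import AnnotationTrack, Recording
from .taxonomy import FINE_CLASSES

DEFAULT_FS = 100.0

_X, _Y, _Z = 0, 1, 2


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class Burst:
    """Intermittent oscillation bursts (wheelchair pushes)."""

    freq_hz: float
    amp_g: float
    axes: tuple[int, ...]
    on_s: tuple[float, float] = (1.0, 2.0)  # burst length range
    off_s: tuple[float, float] = (1.0, 3.0)  # recovery length range


@dataclass(frozen=True)
class ClassSignalModel:
    """Generative model for one behavior class.

    ``periodic`` entries are (frequency Hz, amplitude g, axis index, phase).
    ``ramp_between`` makes gravity alternate between two orientations with
    smooth ramps of duration drawn from ``ramp_s`` (the transitioning class).
    """

    gravity: np.ndarray
    periodic: tuple[tuple[float, float, int, float], ...] = ()
    noise_sd: float = 0.02
    jitter: float = 0.0
    burst: Burst | None = None
    ramp_between: tuple[np.ndarray, np.ndarray] | None = None
    ramp_s: tuple[float, float] = (1.0, 3.0)
    dwell_s: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "gravity", _unit(self.gravity))
        for f, a, ax, _ in self.periodic:
            if f <= 0 or a < 0 or ax not in (0, 1, 2):
                raise ValueError("periodic components need freq > 0, amp >= 0, axis in 0..2")


# Orientations (unit vectors, g). Standing: thigh vertical, x down. Seated
# postures share a near-horizontal thigh; lying tips gravity onto y.
_G_STAND = _unit((1.0, 0.0, 0.0))
_G_SIT = _unit((0.20, 0.10, 0.97))
_G_LIE = _unit((0.05, 0.97, 0.24))


def default_models() -> dict[str, ClassSignalModel]:
    """Default generative models for the 11 fine classes.

    The separability structure mirrors what thigh accelerometry can and
    cannot do: static postures differ by orientation; gaits differ by
    frequency and amplitude; the three seated behaviors (sitting, driving,
    wheelchair) share an orientation and differ only in vibration/burst
    dynamics, making them the hard group.
    """
    return {
        "standing": ClassSignalModel(gravity=_G_STAND, noise_sd=0.012),
        "sitting": ClassSignalModel(gravity=_G_SIT, noise_sd=0.012),
        "lying": ClassSignalModel(gravity=_G_LIE, noise_sd=0.010),
        "walking": ClassSignalModel(
            gravity=_unit((0.98, 0.02, 0.20)),
            periodic=((1.8, 0.35, _X, 0.0), (1.8, 0.18, _Z, np.pi / 2), (3.6, 0.12, _X, 0.7)),
            noise_sd=0.030,
            jitter=0.04,
        ),
        "running": ClassSignalModel(
            gravity=_unit((0.98, 0.02, 0.20)),
            periodic=((2.8, 0.95, _X, 0.0), (2.8, 0.45, _Z, np.pi / 2), (5.6, 0.25, _X, 1.1)),
            noise_sd=0.060,
            jitter=0.04,
        ),
        "ascending_stairs": ClassSignalModel(
            gravity=_unit((0.93, 0.05, 0.36)),
            periodic=((1.6, 0.30, _X, 0.0), (1.6, 0.30, _Z, 1.2)),
            noise_sd=0.035,
            jitter=0.05,
        ),
        "descending_stairs": ClassSignalModel(
            gravity=_unit((0.96, 0.05, 0.27)),
            periodic=((1.7, 0.22, _X, 0.0), (1.7, 0.38, _Z, 2.3), (3.4, 0.10, _X, 0.4)),
            noise_sd=0.035,
            jitter=0.05,
        ),
        "cycling": ClassSignalModel(
            gravity=_unit((0.55, 0.08, 0.83)),
            periodic=((1.4, 0.28, _X, 0.0), (1.4, 0.20, _Z, np.pi / 2)),
            noise_sd=0.015,
            jitter=0.05,
        ),
        "driving": ClassSignalModel(gravity=_unit((0.21, 0.10, 0.97)), noise_sd=0.028),
        "wheelchair": ClassSignalModel(
            gravity=_G_SIT,
            noise_sd=0.018,
            burst=Burst(freq_hz=1.1, amp_g=0.16, axes=(_X, _Y)),
        ),
        "transitioning": ClassSignalModel(
            gravity=_G_SIT,
            noise_sd=0.025,
            ramp_between=(_G_SIT, _G_STAND),
        ),
    }


@dataclass
class SessionScript:
    """An ordered protocol of behavior bouts for one monitoring session."""

    bouts: list[tuple[str, float]]
    seed: int = 0
    fs: float = DEFAULT_FS

    def __post_init__(self) -> None:
        if not self.bouts:
            raise ValueError("session script must contain at least one bout")
        for c, d in self.bouts:
            if c not in FINE_CLASSES:
                raise KeyError(f"unknown behavior class {c!r}")
            if d <= 0:
                raise ValueError(f"bout duration must be positive; got {d}")

    @property
    def total_s(self) -> float:
        return float(sum(d for _, d in self.bouts))


def _gravity_track(model: ClassSignalModel, n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Per-sample gravity vector; constant, or ramping for transitions."""
    if model.ramp_between is None:
        return np.broadcast_to(model.gravity, (n, 3)).copy()
    g_a, g_b = (_unit(model.ramp_between[0]), _unit(model.ramp_between[1]))
    # alternate dwell / ramp / dwell / ramp ... between the two orientations
    track = np.empty((n, 3))
    pos = 0
    cur, nxt = g_a, g_b
    while pos < n:
        dwell = int(rng.uniform(*model.dwell_s) * fs)
        end = min(pos + dwell, n)
        track[pos:end] = cur
        pos = end
        if pos >= n:
            break
        ramp = max(2, int(rng.uniform(*model.ramp_s) * fs))
        end = min(pos + ramp, n)
        # cosine blend keeps |g| close to 1 between nearby orientations
        w = 0.5 * (1 - np.cos(np.pi * np.arange(end - pos) / ramp))
        seg = (1 - w)[:, None] * cur + w[:, None] * nxt
        track[pos:end] = seg / np.linalg.norm(seg, axis=1, keepdims=True)
        pos = end
        cur, nxt = nxt, cur
    return track


def _burst_envelope(burst: Burst, n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    env = np.zeros(n)
    ramp = int(0.2 * fs)
    pos = int(rng.uniform(*burst.off_s) * fs * 0.5)
    while pos < n:
        on = int(rng.uniform(*burst.on_s) * fs)
        end = min(pos + on, n)
        seg = np.ones(end - pos)
        r = min(ramp, len(seg) // 2)
        if r > 0:
            edge = 0.5 * (1 - np.cos(np.pi * np.arange(r) / r))
            seg[:r] = edge
            seg[-r:] = edge[::-1]
        env[pos:end] = seg
        pos = end + int(rng.uniform(*burst.off_s) * fs)
    return env


def simulate_bout(
    class_name: str,
    duration_s: float,
    model: ClassSignalModel | None = None,
    seed: int = 0,
    fs: float = DEFAULT_FS,
) -> Recording:
    """One continuous bout of a single behavior. Deterministic per seed."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if model is None:
        model = default_models()[class_name]
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    a = _gravity_track(model, n, fs, rng)
    for f, amp, axis, phase in model.periodic:
        f_eff = f * (1.0 + rng.uniform(-model.jitter, model.jitter))
        a[:, axis] += amp * np.sin(2 * np.pi * f_eff * t + phase + rng.uniform(0, 2 * np.pi))
    if model.burst is not None:
        env = _burst_envelope(model.burst, n, fs, rng)
        osc = np.sin(2 * np.pi * model.burst.freq_hz * t + rng.uniform(0, 2 * np.pi))
        for axis in model.burst.axes:
            a[:, axis] += model.burst.amp_g * env * osc
    if model.noise_sd > 0:
        a += rng.normal(0.0, model.noise_sd, size=(n, 3))
    return Recording(t=t, a=a, fs=fs)


def _tap_triplet(a: np.ndarray, fs: float, center_s: float, amp_g: float = 3.0) -> None:
    """Inject three sharp spikes (0.15 s apart) into an acceleration array."""
    for k in range(3):
        i = int(round((center_s + 0.15 * k) * fs))
        if 0 <= i < len(a) - 1:
            a[i : i + 2, 0] += amp_g


def simulate_session(
    script: SessionScript,
    models: dict[str, ClassSignalModel] | None = None,
    inject_taps: bool = False,
    crossfade_s: float = 0.5,
    tap_pad_s: float = 3.0,
) -> tuple[Recording, AnnotationTrack]:
    """Concatenate scripted bouts into one annotated recording.

    Consecutive bouts are blended with a ``crossfade_s`` linear cross-fade
    centered on the boundary; annotation intervals match the script exactly.
    With ``inject_taps`` the session is padded with quiet segments carrying a
    triple-tap marker at the start and end (annotations shift accordingly).
    """
    if models is None:
        models = default_models()
    fs = script.fs
    rng = np.random.default_rng(script.seed)
    pad = tap_pad_s if inject_taps else 0.0
    total = script.total_s + 2 * pad
    n_total = int(round(total * fs))
    sig = np.zeros((n_total, 3))
    weight = np.zeros(n_total)
    half = crossfade_s / 2.0

    bounds = np.concatenate([[0.0], np.cumsum([d for _, d in script.bouts])]) + pad
    intervals = []
    n_bouts = len(script.bouts)
    for i, (cls, dur) in enumerate(script.bouts):
        s, e = bounds[i], bounds[i + 1]
        intervals.append((s, e, cls))
        # extend into the cross-fade region (and the tap padding at the ends)
        lead = pad if i == 0 else half
        tail = pad if i == n_bouts - 1 else half
        seed_i = int(rng.integers(0, 2**31 - 1))
        bout = simulate_bout(cls, dur + lead + tail, models[cls], seed=seed_i, fs=fs)
        i0 = int(round((s - lead) * fs))
        n_b = min(len(bout.a), n_total - i0)
        w = np.ones(n_b)
        ramp = int(crossfade_s * fs)
        if i > 0 and ramp > 0:
            w[: min(ramp, n_b)] = np.linspace(0, 1, min(ramp, n_b), endpoint=False)
        if i < n_bouts - 1 and ramp > 0:
            w[-min(ramp, n_b):] = np.minimum(w[-min(ramp, n_b):], np.linspace(1, 0, min(ramp, n_b)))
        sig[i0 : i0 + n_b] += w[:, None] * bout.a[:n_b]
        weight[i0 : i0 + n_b] += w
    weight[weight == 0] = 1.0
    sig /= weight[:, None]
    if inject_taps:
        _tap_triplet(sig, fs, center_s=pad / 3.0)
        _tap_triplet(sig, fs, center_s=total - pad / 3.0 - 0.3)
    t = np.arange(n_total) / fs
    return Recording(t=t, a=sig, fs=fs), AnnotationTrack(intervals)


def _rotation(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    k = _unit(axis)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def subject_models(
    base: dict[str, ClassSignalModel], rng: np.random.Generator
) -> dict[str, ClassSignalModel]:
    """Apply subject-level random effects to a set of class models.

    One device-placement rotation (up to ±10°) shared across classes, an
    amplitude factor U(0.8, 1.25) and a cadence factor U(0.9, 1.1) — enough
    between-subject variation to make subject-held-out evaluation a
    genuinely harder problem than window-level cross-validation.
    """
    rot = _rotation(rng.normal(size=3), np.deg2rad(rng.uniform(-10, 10)))
    amp_f = rng.uniform(0.8, 1.25)
    freq_f = rng.uniform(0.9, 1.1)
    noise_f = rng.uniform(0.8, 1.25)
    out = {}
    for name, m in base.items():
        periodic = tuple((f * freq_f, a * amp_f, ax, ph) for f, a, ax, ph in m.periodic)
        burst = (
            replace(m.burst, amp_g=m.burst.amp_g * amp_f, freq_hz=m.burst.freq_hz * freq_f)
            if m.burst
            else None
        )
        ramp = (
            (rot @ m.ramp_between[0], rot @ m.ramp_between[1]) if m.ramp_between else None
        )
        out[name] = replace(
            m,
            gravity=rot @ m.gravity,
            periodic=periodic,
            burst=burst,
            ramp_between=ramp,
            noise_sd=m.noise_sd * noise_f,
        )
    return out


def simulate_cohort(
    n_subjects: int,
    per_class_minutes: float,
    seed: int = 0,
    fs: float = DEFAULT_FS,
    classes: tuple[str, ...] = FINE_CLASSES,
) -> list[tuple[Recording, AnnotationTrack]]:
    """One annotated session per subject, with subject-level random effects.

    Each subject performs every class once, in a subject-specific random
    order, for ``per_class_minutes`` minutes per bout. The list index is the
    subject id, so leave-one-subject-out evaluation is meaningful.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    base = default_models()
    cohort = []
    for _ in range(n_subjects):
        models = subject_models(base, rng)
        order = list(rng.permutation(np.array(classes, dtype=object)))
        script = SessionScript(
            bouts=[(c, per_class_minutes * 60.0) for c in order],
            seed=int(rng.integers(0, 2**31 - 1)),
            fs=fs,
        )
        cohort.append(simulate_session(script, models))
    return cohort
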