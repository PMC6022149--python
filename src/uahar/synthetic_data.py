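"""Synthetic multi-subject 6-axis IMU streams with labeled activities.

The simulator produces 50-Hz accelerometer (g) + gyroscope (deg/s)
streams for four activity categories so every pipeline stage can be
exercised without recorded data:

* LIA  — upright gravity vector plus low-variance white noise;
* MIA  — gait-like sinusoids near 2 Hz of moderate amplitude on the
  acceleration axes with a small gyroscope oscillation;
* VIA  — faster (~3 Hz), larger-amplitude oscillation on both sensors;
* Fall — a scripted event: 1 s of quiet standing, a 300-ms transient in
  which the gyroscope pulse integrates to a 70-100 degree tilt about the
  x or z axis and the acceleration shows a free-fall dip followed by an
  impact spike, then a still lying posture (rotated gravity).  Transient
  plus the first 0.7 s of lying carry the ``Fall`` label.

Gravity is a constant 1-g vector rotated by the subject's baseline
pitch; falls rotate it by the integrated tilt, so the gravity-separation
filter has realistic work to do.  Subject-to-subject distribution shift
is modeled as a shared per-subject signal-strength multiplier with
small per-class jitter: classes remain separable within a subject while
class boundaries overlap across subjects, which is what makes
personalization measurable.  Everything is reproducible from seeds.

The signal model is deliberately simple — sinusoids, noise, and
scripted transients.  The goal is statistical structure (class
separation, subject shift, fall transients), not biomechanical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_calibration import RawStream

FALL_TRANSIENT_S = 0.3
_FALL_PRE_S = 2.5          # quiet standing before loss of balance (LIA label)
_FALL_LYING_FALL_S = 0.7   # post-impact lying carrying the Fall label
_FALL_LYING_REST_S = 2.5   # further still lying, labeled LIA
_FALL_RECOVERY_S = 4.0     # standing back up: slow rotation + moderate movement
FALL_EVENT_S = (
    _FALL_PRE_S + FALL_TRANSIENT_S + _FALL_LYING_FALL_S
    + _FALL_LYING_REST_S + _FALL_RECOVERY_S
)

#: label for the stand-up segment after a fall; it is part of the continuous
#: stream but is not one of the four evaluated activity categories (the
#: evaluation protocol has no stand-up-from-floor clips)
TRANSITION_LABEL = "Transition"

#: per-class base oscillation amplitudes (g on acceleration, deg/s on gyro)
_CLASS_SIGNAL = {
    "LIA": {"acc_amp": 0.0, "gyro_amp": 0.0, "freq": 0.0, "acc_noise": 0.02, "gyro_noise": 1.5},
    "MIA": {"acc_amp": 0.40, "gyro_amp": 30.0, "freq": 2.0, "acc_noise": 0.05, "gyro_noise": 3.0},
    "VIA": {"acc_amp": 0.85, "gyro_amp": 70.0, "freq": 3.1, "acc_noise": 0.08, "gyro_noise": 5.0},
}


@dataclass
class SubjectProfile:
    """Per-subject signal parameters inducing cross-subject distribution shift."""

    subject_id: int
    amp: dict[str, float] = field(
        default_factory=lambda: {"LIA": 1.0, "MIA": 1.0, "VIA": 1.0}
    )
    base_pitch_deg: float = 0.0
    gait_freq_offset_hz: dict[str, float] = field(
        default_factory=lambda: {"MIA": 0.0, "VIA": 0.0}
    )
    noise: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.amp.values()):
            raise ValueError("amplitude multipliers must be > 0")
        if self.noise < 0:
            raise ValueError("noise level must be >= 0")


@dataclass
class SessionScript:
    """Ordered (activity, duration_s) entries; Fall entries expand to the
    fixed pre/transient/lying structure (duration must equal FALL_EVENT_S)."""

    entries: list[tuple[str, float]]

    def __post_init__(self) -> None:
        for act, dur in self.entries:
            if act not in ("LIA", "MIA", "VIA", "Fall"):
                raise ValueError(f"unknown activity {act!r}")
            if dur <= 0:
                raise ValueError("durations must be > 0")
            if act == "Fall" and abs(dur - FALL_EVENT_S) > 1e-9:
                raise ValueError(f"Fall entries must have duration {FALL_EVENT_S} s")

    def duration_s(self) -> float:
        return sum(d for _, d in self.entries)


def default_train_script() -> SessionScript:
    """Fall-free adaptation session: 80 s each of LIA, MIA, VIA."""
    return SessionScript([("LIA", 80.0), ("MIA", 80.0), ("VIA", 80.0)])


def default_test_script(n_falls: int = 4) -> SessionScript:
    """Held-out session with falls interleaved between activity bouts."""
    entries: list[tuple[str, float]] = [("LIA", 9.0), ("MIA", 9.0), ("VIA", 9.0)]
    for _ in range(n_falls):
        entries.append(("Fall", FALL_EVENT_S))
    return SessionScript(entries)


def default_session_script(n_falls: int = 4) -> SessionScript:
    """Train portion followed by the test portion (falls only at the end)."""
    return SessionScript(default_train_script().entries + default_test_script(n_falls).entries)


def _rot(axis: int, deg: float) -> np.ndarray:
    """Right-handed rotation matrix about the x (0) or z (2) sensor axis."""
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    if axis == 0:
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    if axis == 2:
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)
    raise ValueError("rotation axis must be 0 (x) or 2 (z)")


def _envelope(n: int, rate_hz: float, rng: np.random.Generator,
              depth: float, ctrl_hz: float = 1.0) -> np.ndarray:
    """Slowly varying positive modulation envelope (one control point per
    ~1/ctrl_hz seconds, linearly interpolated)."""
    m = max(int(np.ceil(n * ctrl_hz / rate_hz)) + 2, 2)
    ctrl = np.clip(rng.normal(1.0, depth, size=m), 0.3, None)
    return np.interp(np.arange(n), np.linspace(0, n - 1, m), ctrl)


def _oscillation(n: int, rate_hz: float, freq: float, acc_amp: float,
                 gyro_amp: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Quasi-periodic movement: sinusoids with stride-to-stride amplitude
    modulation (~15%) and frequency wobble (~5%), as in real gait."""
    phase0 = rng.uniform(0, 2 * np.pi, size=6)
    wobble = _envelope(n, rate_hz, rng, depth=0.05)
    phase_t = 2 * np.pi * np.cumsum(freq * wobble) / rate_hz
    def chan(amp, k):
        return amp * _envelope(n, rate_hz, rng, depth=0.15) * np.sin(phase_t + phase0[k])
    acc = np.column_stack([
        chan(0.6 * acc_amp, 0), chan(0.5 * acc_amp, 1), chan(1.0 * acc_amp, 2),
    ])
    gyro = np.column_stack([
        chan(0.7 * gyro_amp, 3), chan(1.0 * gyro_amp, 4), chan(0.7 * gyro_amp, 5),
    ])
    return acc, gyro


def _activity_block(
    profile: SubjectProfile, activity: str, n: int, rate_hz: float,
    gravity: np.ndarray, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    base = _CLASS_SIGNAL[activity]
    amp = profile.amp[activity]
    freq = base["freq"] + profile.gait_freq_offset_hz.get(activity, 0.0)
    acc, gyro = _oscillation(
        n, rate_hz, freq, base["acc_amp"] * amp, base["gyro_amp"] * amp, rng,
    )
    acc += gravity[None, :]
    acc += rng.normal(0.0, base["acc_noise"] * profile.noise, size=(n, 3))
    gyro += rng.normal(0.0, base["gyro_noise"] * profile.noise, size=(n, 3))
    return acc, gyro


def _fall_event(
    profile: SubjectProfile, rate_hz: float, gravity: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Returns (acc, gyro, labels, final_gravity) for one full fall event.

    Quiet standing, a 300-ms transient (gyro pulse integrating to a
    70-100 degree tilt, free-fall dip, impact spike), still lying, and a
    smooth stand-up.  The transient plus the first 0.7 s of lying carry
    the Fall label; still phases are LIA; the stand-up carries the
    ``Transition`` label (not an evaluated category).  The stand-up
    rotation is gradual, so gravity returns to upright without a step
    discontinuity, and its worst-case one-window gyro integral stays
    well below the 60-degree fall tilt threshold.
    """
    n_pre = int(round(_FALL_PRE_S * rate_hz))
    n_tr = int(round(FALL_TRANSIENT_S * rate_hz))
    n_lay_f = int(round(_FALL_LYING_FALL_S * rate_hz))
    n_lay_r = int(round(_FALL_LYING_REST_S * rate_hz))
    n_rec = int(round(_FALL_RECOVERY_S * rate_hz))
    dt = 1.0 / rate_hz

    axis = int(rng.choice([0, 2]))
    theta = float(rng.uniform(70.0, 100.0)) * float(rng.choice([-1.0, 1.0]))

    # quiet standing (LIA-like)
    acc_pre, gyro_pre = _activity_block(profile, "LIA", n_pre, rate_hz, gravity, rng)

    # transient: half-sine gyro pulse integrating exactly to theta
    t = (np.arange(n_tr) + 0.5) * dt
    pulse = np.sin(np.pi * t / FALL_TRANSIENT_S)
    pulse *= theta / (pulse.sum() * dt)  # rectangular integral == theta
    gyro_tr = rng.normal(0.0, 3.0 * profile.noise, size=(n_tr, 3))
    gyro_tr[:, axis] += pulse
    # gravity direction follows the integrated tilt; free-fall dip then impact
    angles = np.cumsum(pulse) * dt
    acc_tr = np.empty((n_tr, 3))
    for i, ang in enumerate(angles):
        acc_tr[i] = _rot(axis, ang) @ gravity
    dip = np.clip(1.0 - 2.2 * np.sin(np.pi * t / FALL_TRANSIENT_S), 0.05, 1.0)
    acc_tr *= dip[:, None]
    impact = float(rng.uniform(2.2, 3.2))
    n_imp = max(3, n_tr // 5)
    acc_tr[-n_imp:, 2] += impact * np.sin(np.pi * np.arange(n_imp) / n_imp)
    acc_tr += rng.normal(0.0, 0.05 * profile.noise, size=(n_tr, 3))

    # lying still under the rotated gravity
    lying_gravity = _rot(axis, theta) @ gravity
    n_lay = n_lay_f + n_lay_r
    acc_lay = lying_gravity[None, :] + rng.normal(0.0, 0.02 * profile.noise, size=(n_lay, 3))
    gyro_lay = rng.normal(0.0, 1.5 * profile.noise, size=(n_lay, 3))

    # stand back up: constant-rate rotation from theta to 0 about the same
    # axis, with moderate movement on top (a stand-up transfer involves
    # limb motion, not a clean rigid rotation)
    rec_rate = -theta / _FALL_RECOVERY_S
    rec_angles = theta + np.cumsum(np.full(n_rec, rec_rate)) * dt
    acc_rec = np.empty((n_rec, 3))
    for i, ang in enumerate(rec_angles):
        acc_rec[i] = _rot(axis, ang) @ gravity
    osc_acc, osc_gyro = _activity_block(
        profile, "MIA", n_rec, rate_hz, np.zeros(3), rng
    )
    acc_rec += osc_acc
    gyro_rec = osc_gyro
    gyro_rec[:, axis] += rec_rate

    acc = np.vstack([acc_pre, acc_tr, acc_lay, acc_rec])
    gyro = np.vstack([gyro_pre, gyro_tr, gyro_lay, gyro_rec])
    labels = np.array(
        ["LIA"] * n_pre + ["Fall"] * (n_tr + n_lay_f) + ["LIA"] * n_lay_r
        + [TRANSITION_LABEL] * n_rec,
        dtype=object,
    )
    return acc, gyro, labels, gravity


def simulate_subject(
    profile: SubjectProfile,
    script: SessionScript,
    rate_hz: float = 50.0,
) -> RawStream:
    """Simulate one labeled session stream; deterministic given profile.seed."""
    rng = np.random.default_rng(profile.seed)
    gravity = _rot(0, profile.base_pitch_deg) @ np.array([0.0, 0.0, 1.0])

    acc_parts, gyro_parts, label_parts = [], [], []
    for activity, dur in script.entries:
        n = int(round(dur * rate_hz))
        if activity == "Fall":
            # the subject stands back up afterwards, so upright gravity persists
            acc, gyro, labels, _ = _fall_event(profile, rate_hz, gravity, rng)
            acc_parts.append(acc)
            gyro_parts.append(gyro)
            label_parts.append(labels)
            continue
        acc, gyro = _activity_block(profile, activity, n, rate_hz, gravity, rng)
        acc_parts.append(acc)
        gyro_parts.append(gyro)
        label_parts.append(np.array([activity] * n, dtype=object))

    data = np.hstack([np.vstack(acc_parts), np.vstack(gyro_parts)])
    return RawStream(data, rate_hz=rate_hz, labels=np.concatenate(label_parts))


@dataclass
class SubjectRecord:
    """One cohort member: profile, full stream, and the index of the first
    test sample (everything before it is the fall-free training split)."""

    profile: SubjectProfile
    stream: RawStream
    train_end: int


def make_profiles(
    n_subjects: int,
    master_seed: int = 0,
    subject_spread: float = 0.3,
) -> list[SubjectProfile]:
    """Draw subject profiles with ±``subject_spread`` signal-strength shift."""
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    root = np.random.SeedSequence(master_seed)
    streams_ss, profile_ss = root.spawn(2)
    stream_seeds = streams_ss.generate_state(n_subjects) % (2**31)
    rng = np.random.default_rng(profile_ss)
    profiles = []
    for i in range(n_subjects):
        strength = 1.0 + rng.uniform(-subject_spread, subject_spread)
        jitter = rng.uniform(-0.1, 0.1, size=3) * (subject_spread / 0.3 if subject_spread else 0.0)
        amp = {
            cls: strength * (1.0 + jitter[j])
            for j, cls in enumerate(("LIA", "MIA", "VIA"))
        }
        scale = subject_spread / 0.3 if subject_spread else 0.0
        profiles.append(
            SubjectProfile(
                subject_id=i,
                amp=amp,
                base_pitch_deg=float(rng.uniform(-10, 10)) * scale,
                gait_freq_offset_hz={
                    "MIA": float(rng.uniform(-0.2, 0.2)) * scale,
                    "VIA": float(rng.uniform(-0.3, 0.3)) * scale,
                },
                noise=float(1.0 + rng.uniform(-0.2, 0.2) * scale),
                seed=int(stream_seeds[i]),
            )
        )
    return profiles


def make_cohort(
    n_subjects: int = 10,
    script: SessionScript | None = None,
    master_seed: int = 0,
    subject_spread: float = 0.3,
    rate_hz: float = 50.0,
    n_falls: int = 4,
    train_s: float | None = None,
) -> list[SubjectRecord]:
    """Simulate a cohort; default script = 180 s fall-free training followed
    by a test portion with falls (4:1 train:test by design).

    For custom scripts pass ``train_s`` (duration of the fall-free training
    prefix); it defaults to the sum of entries before the first fall.
    """
    if script is None:
        script = default_session_script(n_falls=n_falls)
        train_dur = default_train_script().duration_s()
    elif train_s is not None:
        train_dur = train_s
    else:
        # training split = leading fall-free entries
        train_dur = 0.0
        for act, dur in script.entries:
            if act == "Fall":
                break
            train_dur += dur
    train_end = int(round(train_dur * rate_hz))
    records = []
    for profile in make_profiles(n_subjects, master_seed, subject_spread):
        stream = simulate_subject(profile, script, rate_hz=rate_hz)
        records.append(SubjectRecord(profile=profile, stream=stream, train_end=train_end))
    return records
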