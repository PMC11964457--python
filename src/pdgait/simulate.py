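"""Synthetic plantar-VGRF cohort generator.

Emulates the statistical structure the severity classifiers exploit: 100 Hz
sampling, ~2-minute walks, quasi-periodic alternating-foot stance bursts
whose per-sensor force follows a smooth double-peak ("M") profile — a
heel-strike lobe followed by a toe-off lobe — and total-force channels that
are exact sums of their 8 sensors.  Disease severity acts on three knobs
only, chosen to mirror what distinguishes patient recordings from controls:

* ``stance_fraction`` — fraction of the gait cycle with foot–ground contact;
  higher severity prolongs high-pressure durations (slower gait),
* ``asymmetry`` — right/left amplitude ratio; higher severity is more
  asymmetric,
* ``cycle_jitter_sd`` — cycle-to-cycle timing variability, growing with
  severity.

Subject-level parameters (overall amplitude, cadence, baseline stance
fraction) are drawn once per subject so that walks of the same subject are
correlated — a prerequisite for meaningful subject-independent
cross-validation tests.  Not modelled: biomechanical detail, freezing of
gait, treadmill dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GaitDataset, SubjectInfo, WalkRecord

#: Per-sensor peak force in newtons (left foot; right is scaled by asymmetry).
#: Roughly heel (1-3), midfoot (4-5), forefoot/toe (6-8).
DEFAULT_AMPLITUDE = (320.0, 350.0, 260.0, 180.0, 170.0, 230.0, 300.0, 330.0)

#: Heel-lobe weight per sensor; toe-lobe weight is its complement.
_HEEL_WEIGHT = (0.85, 0.80, 0.70, 0.55, 0.45, 0.30, 0.20, 0.15)

_STAGES = ("healthy", "2", "2.5", "3")


@dataclass
class GaitSimConfig:
    """Cohort-level simulation parameters; per-class tuples are indexed 0..3."""

    n_subjects_per_class: int = 10
    walks_per_subject: int = 1
    duration: float = 120.0  # seconds
    sampling_rate: float = 100.0  # Hz
    cadence: float = 1.0  # strides / s
    stance_fraction: tuple[float, float, float, float] = (0.56, 0.63, 0.70, 0.77)
    asymmetry: tuple[float, float, float, float] = (1.0, 0.92, 0.84, 0.76)
    cycle_jitter_sd: tuple[float, float, float, float] = (0.010, 0.018, 0.027, 0.038)
    amplitude_profile: tuple[float, ...] = DEFAULT_AMPLITUDE
    sensor_noise_sd: float = 2.0  # N, per sensor sample
    subject_amp_sd: float = 0.06  # relative, drawn once per subject
    subject_cadence_sd: float = 0.05  # relative
    subject_stance_sd: float = 0.008  # absolute, on stance fraction
    informative_sensors: tuple[int, ...] | None = None  # 1-based; planted-signal mode
    planted_amplitude: tuple[float, float, float, float] = (1.0, 0.85, 0.70, 0.55)
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(
            a < b for a, b in zip(self.stance_fraction, self.stance_fraction[1:])
        ):
            raise ValueError("stance_fraction must increase strictly with severity")
        if not all(
            a <= b for a, b in zip(self.cycle_jitter_sd, self.cycle_jitter_sd[1:])
        ):
            raise ValueError("cycle_jitter_sd must be non-decreasing with severity")
        if len(self.amplitude_profile) != 8:
            raise ValueError("amplitude_profile needs 8 per-sensor peaks")


@dataclass
class _SubjectParams:
    amp: float  # overall amplitude multiplier
    cadence: float  # strides / s
    stance_offset: float  # additive offset on the class stance fraction


def _draw_subject(config: GaitSimConfig, rng: np.random.Generator) -> _SubjectParams:
    return _SubjectParams(
        amp=float(rng.normal(1.0, config.subject_amp_sd)),
        cadence=float(config.cadence * rng.normal(1.0, config.subject_cadence_sd)),
        stance_offset=float(rng.normal(0.0, config.subject_stance_sd)),
    )


def _stance_profile(n: int) -> np.ndarray:
    """Double-peak stance shape on n samples, peak value ~1.

    Two overlapping raised-cosine lobes centred at 27% (heel strike) and 73%
    (toe off) of stance, each spanning 70% of it, giving the characteristic
    "M" with a mid-stance valley around half the peak and non-zero force
    across the whole contact window.  Returned per lobe so sensors can weight
    heel vs toe differently.
    """
    phase = np.linspace(0.0, 1.0, n, endpoint=False)
    lobe = lambda c: 0.5 * (1 + np.cos(2 * np.pi * np.clip((phase - c) / 0.7, -0.5, 0.5)))
    return np.stack([lobe(0.27), lobe(0.73)], axis=1)  # (n, 2)


def _foot_envelope(
    T: int,
    fs: float,
    period: float,
    offset: float,
    stance_frac: float,
    jitter_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Heel/toe lobe envelopes for one foot over T samples -> (T, 2)."""
    env = np.zeros((T, 2))
    n_strides = int(np.ceil(T / fs / period)) + 2
    for i in range(n_strides):
        onset = offset + i * period + rng.normal(0.0, jitter_sd)
        stance_len = stance_frac * period
        i0 = int(round(onset * fs))
        i1 = int(round((onset + stance_len) * fs))
        if i1 <= 0 or i0 >= T:
            continue
        prof = _stance_profile(i1 - i0)
        a, b = max(i0, 0), min(i1, T)
        env[a:b] += prof[a - i0 : b - i0]
    return env


def simulate_walk(
    config: GaitSimConfig,
    class_index: int,
    rng: np.random.Generator,
    subject: _SubjectParams | None = None,
    subject_id: str = "SYN000",
    walk_id: str = "01",
) -> WalkRecord:
    """Simulate one walk of the given severity class.

    With ``sensor_noise_sd=0`` the totals equal the sensor sums exactly by
    construction (noise, when present, is added to the 16 sensors *before*
    summation, so totals remain exact sums in all cases).
    """
    if class_index not in (0, 1, 2, 3):
        raise ValueError(f"class_index must be 0..3, got {class_index}")
    if subject is None:
        subject = _draw_subject(config, rng)
    fs = config.sampling_rate
    period = 1.0 / subject.cadence
    if config.duration < 2 * period:
        raise ValueError("duration must cover at least 2 stride periods")
    T = int(round(config.duration * fs))

    # In planted-signal mode class effects act only on the informative sensors'
    # amplitude/asymmetry; stance timing stays class-independent so the
    # total-force channels (exact sensor sums) carry the class signal only in
    # heavily diluted form.
    informative = config.informative_sensors
    timing_class = 0 if informative is not None else class_index
    sf = float(
        np.clip(config.stance_fraction[timing_class] + subject.stance_offset, 0.3, 0.92)
    )
    jit = config.cycle_jitter_sd[timing_class]
    env_l = _foot_envelope(T, fs, period, 0.0, sf, jit, rng)
    env_r = _foot_envelope(T, fs, period, period / 2, sf, jit, rng)

    amp = np.asarray(config.amplitude_profile) * subject.amp
    asym = config.asymmetry[class_index] if informative is None else config.asymmetry[0]
    hw = np.asarray(_HEEL_WEIGHT)
    weights = np.stack([hw, 1.0 - hw], axis=1)  # (8, 2)

    sensors = np.empty((T, 16))
    for j in range(8):
        factor, a_r = 1.0, asym
        if informative is not None and (j + 1) in informative:
            factor = config.planted_amplitude[class_index]
            a_r = config.asymmetry[class_index]
        sensors[:, j] = factor * amp[j] * (env_l @ weights[j])
        sensors[:, 8 + j] = factor * a_r * amp[j] * (env_r @ weights[j])
    if config.sensor_noise_sd > 0:
        sensors += rng.normal(0.0, config.sensor_noise_sd, sensors.shape)
    np.clip(sensors, 0.0, None, out=sensors)

    forces = np.empty((T, 18))
    forces[:, :16] = sensors
    forces[:, 16] = sensors[:, :8].sum(axis=1)
    forces[:, 17] = sensors[:, 8:].sum(axis=1)
    return WalkRecord(
        subject_id=subject_id,
        time=np.arange(T) / fs,
        forces=forces,
        study="Syn",
        walk_id=walk_id,
        severity_class=class_index,
        group="control" if class_index == 0 else "PD",
        sampling_rate=fs,
        tag="synthetic",
    )


def simulate_cohort(config: GaitSimConfig) -> GaitDataset:
    """Simulate a labelled cohort: ``n_subjects_per_class`` per class,
    ``walks_per_subject`` walks each, reproducible under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    subjects: dict[str, SubjectInfo] = {}
    walks: list[WalkRecord] = []
    for cls in range(4):
        for s in range(config.n_subjects_per_class):
            sid = f"Syn{cls}{s:02d}"
            params = _draw_subject(config, rng)
            subjects[sid] = SubjectInfo(
                subject_id=sid,
                group="control" if cls == 0 else "PD",
                hoehn_yahr=_STAGES[cls],
                study="Syn",
                age=float(np.round(rng.uniform(45, 80), 1)),
                sex=("M", "F")[int(rng.integers(2))],
                height=float(np.round(rng.normal(1.70, 0.08), 2)),
                weight=float(np.round(rng.normal(72, 10), 1)),
            )
            for w in range(config.walks_per_subject):
                walks.append(
                    simulate_walk(
                        config, cls, rng, subject=params, subject_id=sid,
                        walk_id=f"{w + 1:02d}",
                    )
                )
    return GaitDataset(walks=walks, subjects=subjects)


def estimate_stance_fraction(record: WalkRecord, threshold_frac: float = 0.02) -> float:
    """Fraction of samples with total force above ``threshold_frac`` of its peak,
    averaged over feet — a simple contact-time statistic used to verify that the
    simulator's severity gradient is recoverable from the signal."""
    out = []
    for col in (16, 17):
        x = record.forces[:, col]
        peak = float(x.max())
        if peak <= 0:
            return 0.0
        out.append(float(np.mean(x > threshold_frac * peak)))
    return float(np.mean(out))
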