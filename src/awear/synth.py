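"""Synthetic 6-axis wrist-IMU cohort generator.

The clinical recordings behind the assessment protocol are not publicly
available, so this module synthesizes labeled recordings with the same
statistical structure the downstream pipeline assumes:

* three subject classes — ``healthy``, ``tremor`` (Parkinsonian tremor, no
  bradykinesia) and ``bradykinesia`` (no tremor);
* six UPDRS-style upper-limb tasks, 60 s each at 100 Hz;
* rest tremor in the 4-6 Hz Parkinsonian band, postural tremor in 4-12 Hz,
  kinetic tremor in 2-7 Hz;
* bradykinesia as slowed, attenuated voluntary movement with a within-trial
  exponential amplitude decay (the "sequence effect");
* measurement nuisance: broadband Gaussian noise, random-walk drift and
  sparse outlier spikes.

Each channel is a sum of a voluntary sinusoid (per-channel random phase,
exponentially decaying envelope), a tremor sinusoid projected on a random
unit direction vector, Gaussian noise, cumulative random-walk drift and
Poisson-placed outlier spikes.  Gravity offset is deliberately omitted from
the accelerometer channels: the 2 Hz high-pass edge of the standard
preprocessing removes DC anyway, so modeling it would only exercise the
filter, not the features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np

__all__ = [
    "CLASSES",
    "TASKS",
    "TREMOR_BANDS_HZ",
    "GYRO_UNIT_SCALE",
    "MotionModelParams",
    "ClassModel",
    "CohortSpec",
    "Recording",
    "simulate_recording",
    "generate_cohort",
    "default_class_models",
]

CLASSES: Tuple[str, ...] = ("healthy", "tremor", "bradykinesia")

TASKS: Tuple[str, ...] = (
    "rest",
    "postural",
    "kinetic",
    "finger_tap",
    "fist_open_close",
    "pronation_supination",
)

#: Tremor frequency band (Hz) by task. Rest tremor is the 4-6 Hz Parkinsonian
#: band; postural tremor 4-12 Hz; kinetic (action) tremor 2-7 Hz. The three
#: bradykinesia-protocol tasks re-use the rest band (residual tremor during
#: voluntary action stays near the subject's rest frequency).
TREMOR_BANDS_HZ: Dict[str, Tuple[float, float]] = {
    "rest": (4.0, 6.0),
    "postural": (4.0, 12.0),
    "kinetic": (2.0, 7.0),
    "finger_tap": (4.0, 6.0),
    "fist_open_close": (4.0, 6.0),
    "pronation_supination": (4.0, 6.0),
}

#: Amplitude scale applied to voluntary movement, noise and drift on the
#: gyroscope channels, converting the accelerometer-unit (G) magnitudes of
#: the motion model into realistic wrist angular rates (dps). Roughly the
#: ratio of typical tremor angular rate to tremor acceleration.
GYRO_UNIT_SCALE: float = 100.0

CHANNELS: Tuple[str, ...] = ("ax", "ay", "az", "gx", "gy", "gz")


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MotionModelParams:
    """Fully resolved motion-model parameters for one subject x task trial."""

    class_label: str
    task: str
    tremor_freq_hz: float = 0.0
    tremor_amp_g: float = 0.0
    tremor_amp_dps: float = 0.0
    voluntary_freq_hz: float = 0.0
    voluntary_amp: float = 0.0
    amp_decay_rate: float = 0.0  # per-second fractional amplitude decline
    noise_sd: float = 0.0
    drift_sd: float = 0.0  # random-walk step SD
    outlier_rate: float = 0.0  # expected outliers per second
    outlier_magnitude: float = 0.0  # multiples of the clean channel SD
    #: slow amplitude/frequency modulation of the voluntary component.
    #: Human voluntary movement is never strictly periodic; without this the
    #: healthy class would look *more* regular than Parkinsonian tremor
    #: (which is a clinically regular oscillation) and the entropy/dimension
    #: features would invert. Tremor itself stays an unmodulated sinusoid.
    voluntary_am_depth: float = 0.25  # fractional amplitude wobble
    voluntary_fm_rad: float = 1.0  # peak phase wander (radians)

    def validate(self) -> None:
        if self.class_label not in CLASSES:
            raise ValueError(f"unknown class_label {self.class_label!r}")
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        nonneg = (
            "tremor_amp_g",
            "tremor_amp_dps",
            "voluntary_amp",
            "amp_decay_rate",
            "noise_sd",
            "drift_sd",
            "outlier_rate",
            "outlier_magnitude",
            "voluntary_am_depth",
            "voluntary_fm_rad",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.class_label == "healthy":
            if self.tremor_amp_g != 0 or self.tremor_amp_dps != 0:
                raise ValueError("healthy class must have zero tremor amplitude")
            if self.amp_decay_rate != 0:
                raise ValueError("healthy class must have amp_decay_rate = 0")
        if self.class_label == "bradykinesia":
            if self.tremor_amp_g != 0 or self.tremor_amp_dps != 0:
                raise ValueError("bradykinesia class must have zero tremor amplitude")
            if self.amp_decay_rate <= 0:
                raise ValueError("bradykinesia class requires amp_decay_rate > 0")
        if self.class_label == "tremor" and (
            self.tremor_amp_g > 0 or self.tremor_amp_dps > 0
        ):
            lo, hi = TREMOR_BANDS_HZ[self.task]
            if not (lo <= self.tremor_freq_hz <= hi):
                raise ValueError(
                    f"tremor_freq_hz={self.tremor_freq_hz} outside the "
                    f"{lo}-{hi} Hz band for task {self.task!r}"
                )


@dataclass
class Recording:
    """One subject x task 6-channel time series.

    Accelerometer channels (ax, ay, az) are in G; gyroscope channels
    (gx, gy, gz) in degrees per second.  ``t`` is seconds, strictly
    increasing with step 1/sampling_rate_hz.
    """

    subject_id: str
    class_label: str
    task: str
    sampling_rate_hz: float
    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.t)

    def channels(self) -> Dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in CHANNELS}

    def with_channels(self, **arrays: np.ndarray) -> "Recording":
        """Copy of this recording with some channels replaced."""
        new = replace(self)
        for name, arr in arrays.items():
            if name not in CHANNELS:
                raise ValueError(f"unknown channel {name!r}")
            setattr(new, name, np.asarray(arr, dtype=float))
        return new

    def validate(self) -> None:
        n = len(self.t)
        for name in CHANNELS:
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name} length != len(t)")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")

    def __eq__(self, other: object) -> bool:  # sample-exact comparison
        if not isinstance(other, Recording):
            return NotImplemented
        meta = (
            self.subject_id == other.subject_id
            and self.class_label == other.class_label
            and self.task == other.task
            and np.isclose(self.sampling_rate_hz, other.sampling_rate_hz)
        )
        if not meta:
            return False
        return all(
            np.array_equal(getattr(self, c), getattr(other, c))
            for c in ("t",) + CHANNELS
        )


@dataclass(frozen=True)
class ClassModel:
    """Between-subject parameter distribution for one class.

    Per-task dictionaries give the class mean; ``*_jitter`` entries are
    relative (fractional) between-subject SDs, truncated at zero.
    """

    class_label: str
    tremor_amp_g_mean: float = 0.0
    tremor_amp_dps_mean: float = 0.0
    tremor_amp_jitter: float = 0.0  # relative SD of subject tremor amplitude
    #: task -> multiplicative attenuation of the subject tremor amplitude
    tremor_task_scale: Dict[str, float] = field(default_factory=dict)
    #: task -> (center Hz, SD Hz); draws are clipped to TREMOR_BANDS_HZ
    tremor_freq: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    voluntary_freq_hz: Dict[str, float] = field(default_factory=dict)
    voluntary_amp: Dict[str, float] = field(default_factory=dict)
    voluntary_freq_jitter: float = 0.08
    voluntary_amp_jitter: float = 0.30
    amp_decay_rate_mean: float = 0.0
    amp_decay_rate_jitter: float = 0.3
    noise_sd_mean: float = 0.02
    noise_sd_jitter: float = 0.45
    drift_sd: float = 1e-3
    outlier_rate: float = 0.2
    outlier_magnitude: float = 8.0
    voluntary_am_depth: float = 0.35
    voluntary_fm_rad: float = 1.5

    def draw_subject(self, rng: np.random.Generator) -> Dict[str, float]:
        """Draw one subject's latent multipliers/values."""

        def jittered(mean: float, rel_sd: float) -> float:
            return max(0.0, mean * (1.0 + rel_sd * rng.standard_normal()))

        return {
            "tremor_amp_scale": max(
                0.05, 1.0 + self.tremor_amp_jitter * rng.standard_normal()
            ),
            "voluntary_freq_scale": max(
                0.3, 1.0 + self.voluntary_freq_jitter * rng.standard_normal()
            ),
            "voluntary_amp_scale": max(
                0.1, 1.0 + self.voluntary_amp_jitter * rng.standard_normal()
            ),
            "amp_decay_rate": jittered(
                self.amp_decay_rate_mean, self.amp_decay_rate_jitter
            )
            if self.amp_decay_rate_mean > 0
            else 0.0,
            "noise_sd": max(
                0.25 * self.noise_sd_mean,
                jittered(self.noise_sd_mean, self.noise_sd_jitter),
            ),
        }

    def task_params(
        self, task: str, subject: Dict[str, float], rng: np.random.Generator
    ) -> MotionModelParams:
        """Resolve the trial-level MotionModelParams for one task."""
        amp_g = self.tremor_amp_g_mean * subject["tremor_amp_scale"]
        amp_dps = self.tremor_amp_dps_mean * subject["tremor_amp_scale"]
        scale = self.tremor_task_scale.get(task, 1.0)
        amp_g *= scale
        amp_dps *= scale
        if amp_g > 0 and task in self.tremor_freq:
            center, sd = self.tremor_freq[task]
            lo, hi = TREMOR_BANDS_HZ[task]
            freq = float(np.clip(center + sd * rng.standard_normal(), lo, hi))
        else:
            freq, amp_g, amp_dps = 0.0, 0.0, 0.0
        vf = self.voluntary_freq_hz.get(task, 0.0) * subject["voluntary_freq_scale"]
        va = self.voluntary_amp.get(task, 0.0) * subject["voluntary_amp_scale"]
        return MotionModelParams(
            class_label=self.class_label,
            task=task,
            tremor_freq_hz=freq,
            tremor_amp_g=amp_g,
            tremor_amp_dps=amp_dps,
            voluntary_freq_hz=vf if va > 0 else 0.0,
            voluntary_amp=va,
            amp_decay_rate=subject["amp_decay_rate"],
            noise_sd=subject["noise_sd"],
            drift_sd=self.drift_sd,
            outlier_rate=self.outlier_rate,
            outlier_magnitude=self.outlier_magnitude,
            voluntary_am_depth=self.voluntary_am_depth,
            voluntary_fm_rad=self.voluntary_fm_rad,
        )


def default_class_models() -> Dict[str, ClassModel]:
    """Frozen default motion models for the three classes.

    Healthy older adults: no tremor, voluntary task movement at 2-2.8 Hz
    (comfortable fast tapping / alternation rates for the 60+ age group).
    Tremor class: Parkinsonian rest tremor around 5 Hz, strongest at rest
    (activation rest > postural/kinetic), healthy-like voluntary movement
    (no bradykinesia sign).  Bradykinesia class: no tremor, voluntary rate
    and amplitude well below healthy, with a 2%/s within-trial amplitude
    decay (sequence effect).  Noise/drift/outlier levels are shared across
    classes and were calibrated once so that the nonlinear and spectral
    features dominate the ANOVA ranking on the default cohort, then frozen.
    """
    healthy_vf = {
        "rest": 0.0,
        "postural": 0.0,
        "kinetic": 2.0,
        "finger_tap": 2.8,
        "fist_open_close": 2.4,
        "pronation_supination": 2.5,
    }
    healthy_va = {
        "rest": 0.0,
        "postural": 0.0,
        "kinetic": 0.08,
        "finger_tap": 0.12,
        "fist_open_close": 0.10,
        "pronation_supination": 0.10,
    }
    healthy = ClassModel(class_label="healthy", voluntary_freq_hz=healthy_vf,
                         voluntary_amp=healthy_va)
    tremor = ClassModel(
        class_label="tremor",
        tremor_amp_g_mean=0.15,
        tremor_amp_dps_mean=25.0,
        tremor_amp_jitter=0.25,
        tremor_task_scale={
            "rest": 1.0,
            "postural": 0.7,
            "kinetic": 0.7,
            "finger_tap": 0.7,
            "fist_open_close": 0.7,
            "pronation_supination": 0.7,
        },
        tremor_freq={
            "rest": (5.0, 0.4),
            "postural": (6.5, 1.5),
            "kinetic": (4.5, 1.0),
            "finger_tap": (5.0, 0.4),
            "fist_open_close": (5.0, 0.4),
            "pronation_supination": (5.0, 0.4),
        },
        voluntary_freq_hz=healthy_vf,
        voluntary_amp=healthy_va,
    )
    brady = ClassModel(
        class_label="bradykinesia",
        voluntary_freq_hz={k: 0.55 * v for k, v in healthy_vf.items()},
        voluntary_amp={k: 0.4 * v for k, v in healthy_va.items()},
        amp_decay_rate_mean=0.02,
    )
    return {"healthy": healthy, "tremor": tremor, "bradykinesia": brady}


@dataclass
class CohortSpec:
    """Full parameterization of a synthetic study cohort."""

    n_healthy: int = 20
    n_tremor: int = 10
    n_bradykinesia: int = 10
    tasks: Tuple[str, ...] = TASKS
    sampling_rate_hz: float = 100.0
    duration_s: float = 60.0
    class_models: Dict[str, ClassModel] = field(default_factory=default_class_models)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_healthy, self.n_tremor, self.n_bradykinesia) < 0:
            raise ValueError("class counts must be >= 0")
        if self.n_healthy + self.n_tremor + self.n_bradykinesia == 0:
            raise ValueError("cohort must contain at least one subject")
        if len(self.tasks) == 0:
            raise ValueError("at least one task required")
        for t in self.tasks:
            if t not in TASKS:
                raise ValueError(f"unknown task {t!r}")
        if self.sampling_rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("sampling_rate_hz and duration_s must be positive")


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------


def _random_direction(rng: np.random.Generator, min_component: float = 0.25) -> np.ndarray:
    """Unit 3-vector with every component's magnitude >= min_component.

    Keeps the tremor oscillation visible on all three sensor axes; a tremor
    exactly orthogonal to an axis is physically implausible for a wrist-worn
    device and would make that axis's band features uninformative.
    """
    while True:
        v = rng.standard_normal(3)
        norm = np.linalg.norm(v)
        if norm < 1e-12:
            continue
        v /= norm
        if np.min(np.abs(v)) >= min_component:
            return v


def simulate_recording(
    params: MotionModelParams,
    fs: float,
    duration: float,
    seed,
    subject_id: str = "S00",
) -> Recording:
    """Synthesize one 6-channel trial from a resolved motion model.

    Channel model: voluntary sinusoid with exponentially decaying envelope
    (random phase per channel) + tremor sinusoid projected on a random unit
    direction (one per sensor family) + white Gaussian noise + random-walk
    drift + sparse outlier spikes. Deterministic under a fixed seed.
    """
    params.validate()
    if fs <= 0 or duration <= 0:
        raise ValueError("fs and duration must be positive")
    for f in (params.tremor_freq_hz, params.voluntary_freq_hz):
        if f >= fs / 2:
            raise ValueError(f"component frequency {f} Hz is at/above Nyquist ({fs/2} Hz)")
    rng = np.random.default_rng(seed)
    n = int(round(fs * duration))
    t = np.arange(n) / fs

    dir_acc = _random_direction(rng)
    dir_gyro = _random_direction(rng)
    tremor_phase_acc = rng.uniform(0, 2 * np.pi)
    tremor_phase_gyro = rng.uniform(0, 2 * np.pi)
    envelope = params.voluntary_amp * np.exp(-params.amp_decay_rate * t)

    def slow_process() -> np.ndarray:
        """Smooth ~unit-SD random process from three low-frequency tones."""
        s = np.zeros(n)
        for _ in range(3):
            a = rng.standard_normal() / np.sqrt(3.0)
            f = rng.uniform(0.1, 0.5)
            th = rng.uniform(0, 2 * np.pi)
            s += a * np.sin(2 * np.pi * f * t + th)
        return s * np.sqrt(2.0)

    # one movement per trial: the modulation is shared across channels,
    # only the projection phase differs
    am = (
        np.clip(1.0 + params.voluntary_am_depth * slow_process(), 0.1, None)
        if params.voluntary_amp > 0
        else 1.0
    )
    pm = (
        params.voluntary_fm_rad * slow_process()
        if params.voluntary_amp > 0
        else 0.0
    )

    data: Dict[str, np.ndarray] = {}
    for i, name in enumerate(CHANNELS):
        is_gyro = name.startswith("g")
        unit = GYRO_UNIT_SCALE if is_gyro else 1.0
        x = np.zeros(n)
        if params.voluntary_amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            x = x + unit * envelope * am * np.sin(
                2 * np.pi * params.voluntary_freq_hz * t + phase + pm
            )
        tremor_amp = params.tremor_amp_dps if is_gyro else params.tremor_amp_g
        if tremor_amp > 0:
            direction = dir_gyro if is_gyro else dir_acc
            phase = tremor_phase_gyro if is_gyro else tremor_phase_acc
            x = x + tremor_amp * direction[i % 3] * np.sin(
                2 * np.pi * params.tremor_freq_hz * t + phase
            )
        if params.noise_sd > 0:
            x = x + rng.normal(0.0, params.noise_sd * unit, n)
        if params.drift_sd > 0:
            x = x + np.cumsum(rng.normal(0.0, params.drift_sd * unit, n))
        if params.outlier_rate > 0 and params.outlier_magnitude > 0:
            n_out = rng.poisson(params.outlier_rate * duration)
            if n_out > 0:
                idx = rng.choice(n, size=min(n_out, n), replace=False)
                sd = float(np.std(x))
                signs = rng.choice([-1.0, 1.0], size=len(idx))
                x = x.copy()
                x[idx] += signs * params.outlier_magnitude * sd
        data[name] = x

    return Recording(
        subject_id=subject_id,
        class_label=params.class_label,
        task=params.task,
        sampling_rate_hz=fs,
        t=t,
        **data,
    )


def generate_cohort(spec: CohortSpec) -> Tuple[List[Recording], List[str]]:
    """Generate the full cohort: one Recording per subject per task.

    Returns a flat recording list (grouped by subject, tasks in spec order)
    and the aligned class-label list. Bit-identical under a fixed
    ``spec.seed``.
    """
    spec.validate()
    prefix = {"healthy": "H", "tremor": "T", "bradykinesia": "B"}
    roster: List[Tuple[str, str]] = []  # (class_label, subject_id)
    for label, count in (
        ("healthy", spec.n_healthy),
        ("tremor", spec.n_tremor),
        ("bradykinesia", spec.n_bradykinesia),
    ):
        roster += [(label, f"{prefix[label]}{i + 1:02d}") for i in range(count)]

    root = np.random.SeedSequence(spec.seed)
    subject_seeds = root.spawn(len(roster))
    recordings: List[Recording] = []
    labels: List[str] = []
    for (label, sid), sseq in zip(roster, subject_seeds):
        model = spec.class_models[label]
        children = sseq.spawn(len(spec.tasks) + 1)
        subj_rng = np.random.default_rng(children[0])
        subject = model.draw_subject(subj_rng)
        for task, cseq in zip(spec.tasks, children[1:]):
            task_rng = np.random.default_rng(cseq)
            params = model.task_params(task, subject, task_rng)
            rec = simulate_recording(
                params,
                spec.sampling_rate_hz,
                spec.duration_s,
                seed=cseq.spawn(1)[0],
                subject_id=sid,
            )
            recordings.append(rec)
            labels.append(label)
    return recordings, labels
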