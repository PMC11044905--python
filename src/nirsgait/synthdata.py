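"""Synthetic prefrontal fNIRS cohorts with a Beer-Lambert forward model.

The real study population (community-dwelling adults >= 65 performing
single-task walking STW, dual-task walking DTW and standing alphabet
recitation STA) is not publicly deposited, so this module generates raw
dual-wavelength intensity recordings whose statistical structure matches
what is reported about it:

* DTW takes longer on average than STW (right-skewed duration distributions);
* Hb task-epoch values are near-zero Gaussian under all conditions with the
  largest spread under DTW;
* HbO2 task-epoch values are shifted positive for STA and more so for DTW;
* per-voxel amplitude variability, missing voxels, motion spikes, slow
  drift and physiological oscillations (Mayer waves ~0.1 Hz, respiration
  ~0.25 Hz, an aliased cardiac component).

The hemodynamic response itself is modeled minimally: a condition-specific
mean shift entering through a linear onset/offset ramp plus AR(1) voxel
noise. Only the marginal distributions are constrained by the source data,
and this is the simplest shape reproducing them.

``forward_intensity`` maps concentration series to detector intensities with
the same modified Beer-Lambert law the preprocessing stage inverts, so the
generator doubles as an oracle for the MBLL conversion.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .optics import OpticalParams

CONDITIONS = ("STW", "DTW", "STA")

# All 6 condition orders; subjects cycle through them (Latin-square
# counterbalancing keyed by subject index).
CONDITION_ORDERS = tuple(itertools.permutations(CONDITIONS))


@dataclass(frozen=True)
class SubjectProfile:
    """Demographics and latent per-subject factors of one participant."""

    subject_id: str
    age: float
    gender: str  # "F" | "M"
    cognitive_score: float
    gain: float = 1.0  # multiplies hemodynamic response amplitudes
    pace: float = 1.0  # multiplies walking-task durations

    def __post_init__(self) -> None:
        if self.age < 65:
            raise ValueError("cohort is restricted to age >= 65")
        if self.gender not in ("F", "M"):
            raise ValueError("gender must be 'F' or 'M'")
        if self.gain <= 0 or self.pace <= 0:
            raise ValueError("subject gain and pace factors must be positive")


@dataclass(frozen=True)
class TaskBlock:
    condition: str
    baseline_start: float  # s; 10-s proximal baseline precedes the task
    task_start: float
    task_end: float

    @property
    def duration(self) -> float:
        return self.task_end - self.task_start


@dataclass(frozen=True)
class TaskSchedule:
    """One session: exactly one STW, DTW and STA block, non-overlapping."""

    blocks: tuple[TaskBlock, ...]
    baseline_duration: float = 10.0

    def __post_init__(self) -> None:
        conds = [b.condition for b in self.blocks]
        if sorted(conds) != sorted(CONDITIONS):
            raise ValueError("schedule must contain exactly one block per condition")
        prev_end = -np.inf
        for b in self.blocks:
            if not (b.baseline_start < b.task_start < b.task_end):
                raise ValueError(f"block times must strictly increase: {b}")
            if b.task_start - b.baseline_start < self.baseline_duration - 1e-9:
                raise ValueError("proximal baseline shorter than baseline_duration")
            if b.baseline_start < prev_end:
                raise ValueError("blocks overlap")
            prev_end = b.task_end
        sta = self.block("STA")
        if abs(sta.duration - 30.0) > 1e-9:
            raise ValueError("STA recitation block must last exactly 30 s")

    def block(self, condition: str) -> TaskBlock:
        for b in self.blocks:
            if b.condition == condition:
                return b
        raise KeyError(condition)

    @property
    def end(self) -> float:
        return max(b.task_end for b in self.blocks)

    def to_json(self) -> str:
        return json.dumps(
            {
                "baseline_duration": self.baseline_duration,
                "blocks": [asdict(b) for b in self.blocks],
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "TaskSchedule":
        d = json.loads(s)
        return cls(
            blocks=tuple(TaskBlock(**b) for b in d["blocks"]),
            baseline_duration=d["baseline_duration"],
        )


def _positive(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value}")


def _probability(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass
class SynthConfig:
    """Generator settings. Defaults encode the emulated study conditions.

    Concentration quantities are in arbitrary micromolar-scale units (the
    source histograms carry no absolute units); intensities are in arbitrary
    detector units with baseline level ``i0`` and hard ceiling
    ``detector_max``.
    """

    n_subjects: int = 100
    fs: float = 2.0
    n_voxels: int = 16
    wavelengths: tuple[float, float] = (730.0, 850.0)
    i0: tuple[float, float] = (1000.0, 1000.0)
    detector_max: float = 4000.0

    # condition-level hemodynamics (uM): STW ~ 0 < STA < DTW for HbO2,
    # small negative Hb shifts, DTW noisiest
    hbo2_shift: dict = field(default_factory=lambda: {"STW": 0.0, "STA": 0.5, "DTW": 1.0})
    hb_shift: dict = field(default_factory=lambda: {"STW": -0.02, "STA": -0.05, "DTW": -0.08})
    hbo2_noise_sd: dict = field(default_factory=lambda: {"STW": 0.2, "STA": 0.2, "DTW": 0.3})
    hb_noise_sd: dict = field(default_factory=lambda: {"STW": 0.12, "STA": 0.12, "DTW": 0.2})
    rest_noise_sd: float = 0.12
    ar_coeff: float = 0.9  # AR(1) pole of voxel noise at 2 Hz
    onset_ramp: float = 10.0  # s, linear rise/fall of the task response
    voxel_gain_sd: float = 0.2  # log-sd of per-voxel response gains

    # walking durations: lognormal, DTW longer, truncated to [20, 180] s
    stw_duration_median: float = 45.0
    dtw_duration_median: float = 60.0
    duration_log_sd: float = 0.25
    duration_bounds: tuple[float, float] = (20.0, 180.0)
    sta_duration: float = 30.0

    # nuisance structure (concentration domain)
    drift_amp: float = 0.15  # uM, slow wander
    drift_period: float = 400.0  # s
    mayer_amp: float = 0.05  # uM at ~0.1 Hz
    mayer_freq: float = 0.1
    resp_amp: float = 0.03  # uM at ~0.25 Hz
    resp_freq: float = 0.25
    cardiac_amp: float = 0.02  # uM, cardiac alias at 2 Hz sampling
    cardiac_freq: float = 0.9

    # nuisance structure (intensity domain)
    shot_noise_frac: float = 0.003  # multiplicative, fraction of signal
    spike_rate: float = 0.005  # spikes per second per voxel-wavelength
    spike_magnitude: float = 0.25  # fraction of i0
    saturation_prob: float = 0.01  # per voxel: clipped-at-ceiling episode
    dark_prob: float = 0.005  # per voxel: dark-current episode
    missing_prob: float = 0.05  # per voxel hardware dropout

    # cohort demographics (age years, RBANS-like cognitive index)
    age_mean: float = 76.16
    age_sd: float = 6.67
    female_fraction: float = 223 / 451
    cognitive_mean: float = 91.77
    cognitive_sd: float = 11.71
    subject_gain_log_sd: float = 0.3
    subject_pace_log_sd: float = 0.2

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for name in ("saturation_prob", "dark_prob", "missing_prob", "female_fraction"):
            _probability(name, getattr(self, name))
        for name in (
            "drift_amp", "mayer_amp", "resp_amp", "cardiac_amp", "shot_noise_frac",
            "spike_rate", "spike_magnitude", "rest_noise_sd", "voxel_gain_sd",
        ):
            _positive(name, getattr(self, name))
        for d in (self.hbo2_noise_sd, self.hb_noise_sd):
            for c, v in d.items():
                _positive(f"noise sd[{c}]", v)
        if not self.dtw_duration_median > self.stw_duration_median:
            raise ValueError("DTW mean duration must exceed STW")
        if not 0 <= self.ar_coeff < 1:
            raise ValueError("ar_coeff must be in [0, 1)")


@dataclass
class RawRecording:
    """One subject's raw session: dual-wavelength intensities plus markers."""

    intensities: np.ndarray  # [2 wavelengths, n_voxels, T], detector units
    fs: float
    schedule: TaskSchedule
    profile: SubjectProfile
    missing_voxels: frozenset = frozenset()  # 1-based voxel indices
    detector_max: float = 4000.0
    ground_truth: dict | None = None  # {"hbo2": [V,T], "hb": [V,T]} if synthetic

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3 or self.intensities.shape[0] != 2:
            raise ValueError("intensities must have shape [2, n_voxels, T]")
        if self.intensities.shape[2] < int(round(self.schedule.end * self.fs)):
            raise ValueError("recording shorter than schedule end")

    @property
    def n_voxels(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[2]


# ---------------------------------------------------------------------------
# seeded sub-streams: one master seed, fixed per-subject / per-stage offsets

_STAGE = {"profile": 1, "schedule": 2, "hemo": 3, "optics": 4, "missing": 5}


def _rng(seed: int, subject: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, subject, _STAGE[stage]])


def make_profile(config: SynthConfig, seed: int, subject_index: int = 0) -> SubjectProfile:
    rng = _rng(seed, subject_index, "profile")
    age = max(65.0, rng.normal(config.age_mean, config.age_sd))
    gender = "F" if rng.random() < config.female_fraction else "M"
    cog = rng.normal(config.cognitive_mean, config.cognitive_sd)
    gain = float(np.exp(rng.normal(0.0, config.subject_gain_log_sd)))
    pace = float(np.exp(rng.normal(0.0, config.subject_pace_log_sd)))
    return SubjectProfile(
        subject_id=f"S{subject_index:04d}", age=float(age), gender=gender,
        cognitive_score=float(cog), gain=gain, pace=pace,
    )


def _draw_duration(median: float, config: SynthConfig, pace: float,
                   rng: np.random.Generator) -> float:
    d = float(np.exp(np.log(median * pace) + rng.normal(0.0, config.duration_log_sd)))
    lo, hi = config.duration_bounds
    return float(np.clip(d, lo, hi))


def make_schedule(config: SynthConfig, seed: int, subject_index: int = 0,
                  profile: SubjectProfile | None = None) -> TaskSchedule:
    """Counterbalanced session schedule with 10-s proximal baselines.

    The condition order cycles through the 6 permutations by subject index;
    STW/DTW durations are subject-paced lognormal draws, STA is fixed 30 s.
    """
    rng = _rng(seed, subject_index, "schedule")
    pace = profile.pace if profile is not None else 1.0
    order = CONDITION_ORDERS[subject_index % len(CONDITION_ORDERS)]
    durations = {
        "STW": _draw_duration(config.stw_duration_median, config, pace, rng),
        "DTW": _draw_duration(config.dtw_duration_median, config, pace, rng),
        "STA": config.sta_duration,
    }
    blocks = []
    t = 20.0  # initial rest, used to estimate reference intensity
    for cond in order:
        baseline_start = t
        task_start = baseline_start + 10.0
        task_end = task_start + durations[cond]
        blocks.append(TaskBlock(cond, baseline_start, task_start, task_end))
        t = task_end + 20.0
    return TaskSchedule(blocks=tuple(blocks))


def _ar1(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    """Unit-marginal-variance AR(1) noise."""
    e = rng.standard_normal(n)
    if rho == 0:
        return e
    from scipy.signal import lfilter

    return lfilter([np.sqrt(1.0 - rho * rho)], [1.0, -rho], e)


def _ramp_profile(t: np.ndarray, block: TaskBlock, onset: float) -> np.ndarray:
    """0 -> 1 linear rise over ``onset`` s at task start, plateau, fall after end."""
    rise = np.clip((t - block.task_start) / max(onset, 1e-9), 0.0, 1.0)
    fall = np.clip(1.0 - (t - block.task_end) / max(onset, 1e-9), 0.0, 1.0)
    return np.where(t < block.task_start, 0.0, np.minimum(rise, fall))


def simulate_hemodynamics(
    profile: SubjectProfile,
    schedule: TaskSchedule,
    config: SynthConfig,
    seed: int,
    subject_index: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel (dHbO2, dHb) series of shape [n_voxels, T] in uM.

    Task response = condition shift x subject gain x per-voxel gain entering
    through a linear onset ramp; plus condition-modulated AR(1) noise, slow
    drift, and Mayer/respiratory/cardiac oscillations.
    """
    config.validate()
    rng = _rng(seed, subject_index, "hemo")
    fs, nv = config.fs, config.n_voxels
    n = int(round((schedule.end + 20.0) * fs))
    t = np.arange(n) / fs

    ramps = {c: _ramp_profile(t, schedule.block(c), config.onset_ramp) for c in CONDITIONS}
    in_task = {
        c: (t >= schedule.block(c).task_start) & (t < schedule.block(c).task_end)
        for c in CONDITIONS
    }

    out = []
    for shifts, noise_sd, osc_scale, drift_scale in (
        (config.hbo2_shift, config.hbo2_noise_sd, 1.0, 1.0),
        (config.hb_shift, config.hb_noise_sd, 0.3, 0.5),
    ):
        series = np.zeros((nv, n))
        sd_env = np.full(n, config.rest_noise_sd)
        for c in CONDITIONS:
            sd_env[in_task[c]] = noise_sd[c]
        for v in range(nv):
            vox_gain = float(np.exp(rng.normal(0.0, config.voxel_gain_sd)))
            resp = np.zeros(n)
            for c in CONDITIONS:
                resp += shifts[c] * profile.gain * vox_gain * ramps[c]
            noise = _ar1(rng, n, config.ar_coeff) * sd_env
            drift = drift_scale * config.drift_amp * (
                np.sin(2 * np.pi * t / config.drift_period + rng.uniform(0, 2 * np.pi))
                + rng.uniform(-1, 1) * (t / max(t[-1], 1.0))
            ) if config.drift_amp > 0 else 0.0
            osc = np.zeros(n)
            for amp, f in (
                (config.mayer_amp, config.mayer_freq),
                (config.resp_amp, config.resp_freq),
                (config.cardiac_amp, config.cardiac_freq),
            ):
                if amp > 0:
                    osc += osc_scale * amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
            series[v] = resp + noise + drift + osc
        out.append(series)
    return out[0], out[1]


def forward_intensity(
    conc: tuple[np.ndarray, np.ndarray],
    optics: OpticalParams,
    config: SynthConfig,
    seed: int,
    subject_index: int = 0,
    schedule: TaskSchedule | None = None,
    profile: SubjectProfile | None = None,
    missing_voxels: frozenset = frozenset(),
) -> np.ndarray:
    """Beer-Lambert forward model: concentrations -> detector intensities.

    ``I(l, t) = I0(l) * 10^(-(eps_HbO2(l)*dHbO2 + eps_Hb(l)*dHb) * d * DPF(l))``
    with configured shot noise, motion spikes, saturation/dark episodes and
    missing-voxel dropouts applied on top. With all noise terms zero the
    MBLL inversion recovers ``conc`` exactly.

    Returns the intensity array [2, n_voxels, T]; use :func:`make_recording`
    or :func:`make_cohort` for a fully assembled :class:`RawRecording`.
    """
    if optics.i0 is None or any(v <= 0 for v in optics.i0):
        raise ValueError("forward model requires strictly positive reference intensities")
    hbo2, hb = (np.asarray(a, dtype=float) for a in conc)
    if hbo2.shape != hb.shape or hbo2.ndim != 2:
        raise ValueError("concentration arrays must both be [n_voxels, T]")
    rng = _rng(seed, subject_index, "optics")
    nv, n = hbo2.shape
    pathlen = optics.pathlength  # [2]
    eps = optics.epsilon
    od = (
        eps[:, 0][:, None, None] * hbo2[None] + eps[:, 1][:, None, None] * hb[None]
    ) * pathlen[:, None, None]
    i0 = np.asarray(optics.i0, dtype=float)
    intens = i0[:, None, None] * 10.0 ** (-od)

    if config.shot_noise_frac > 0:
        intens = intens * (1.0 + config.shot_noise_frac * rng.standard_normal(intens.shape))
    if config.spike_rate > 0 and config.spike_magnitude > 0:
        for w in range(2):
            for v in range(nv):
                k = rng.poisson(config.spike_rate * n / config.fs)
                for _ in range(k):
                    pos = rng.integers(0, n)
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    width = int(rng.integers(1, 4))
                    idx = np.arange(pos, min(pos + width, n))
                    decay = np.exp(-(idx - pos) / 1.5)
                    intens[w, v, idx] += sign * config.spike_magnitude * i0[w] * decay
    for v in range(nv):
        if config.saturation_prob > 0 and rng.random() < config.saturation_prob:
            a = int(rng.integers(0, max(1, n - 12)))
            intens[:, v, a : a + int(rng.integers(4, 13))] = config.detector_max
        if config.dark_prob > 0 and rng.random() < config.dark_prob:
            a = int(rng.integers(0, max(1, n - 12)))
            intens[:, v, a : a + int(rng.integers(4, 13))] = 0.002 * config.detector_max

    dark_floor = 1e-3 * config.detector_max
    for v in sorted(missing_voxels):
        intens[:, v - 1, :] = dark_floor * (1.0 + 0.01 * rng.standard_normal((2, n)))
    np.clip(intens, 1e-6, config.detector_max, out=intens)
    return intens


def make_recording(config: SynthConfig, seed: int, subject_index: int = 0) -> RawRecording:
    """Assemble one subject's :class:`RawRecording` (with ground truth)."""
    config.validate()
    profile = make_profile(config, seed, subject_index)
    schedule = make_schedule(config, seed, subject_index, profile)
    hbo2, hb = simulate_hemodynamics(profile, schedule, config, seed, subject_index)
    rng = _rng(seed, subject_index, "missing")
    missing = frozenset(
        int(v + 1) for v in range(config.n_voxels) if rng.random() < config.missing_prob
    )
    optics = OpticalParams(wavelengths=config.wavelengths, i0=config.i0, age=profile.age)
    intens = forward_intensity(
        (hbo2, hb), optics, config, seed, subject_index, missing_voxels=missing,
    )
    return RawRecording(
        intensities=intens, fs=config.fs, schedule=schedule, profile=profile,
        missing_voxels=missing, detector_max=config.detector_max,
        ground_truth={"hbo2": hbo2, "hb": hb},
    )


def make_cohort(config: SynthConfig, seed: int) -> list[RawRecording]:
    """Generate ``config.n_subjects`` labeled recordings, deterministically."""
    config.validate()
    return [make_recording(config, seed, i) for i in range(config.n_subjects)]
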