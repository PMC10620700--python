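"""Seeded synthetic auditory-oddball sessions and two-group cohorts.

The generator emulates the study conditions the analysis assumes: 320-stimulus
oddball sequences (64 target tones at 2,000 Hz among 256 standard tones at
750 Hz), two prefrontal EEG channels (Fp1, Fp2) sampled at 250 Hz carrying
pink background noise, an alpha-band oscillation, a negative N100 bump for
every stimulus and a positive Gaussian P300 bump for every target, plus
key-press responses with ex-Gaussian latencies governed by per-subject hit
and commission rates.  Subject-level parameters are drawn from truncated
normal distributions calibrated to the reference cohort summaries in
:mod:`oddballerp.calibration`.

Everything is deterministic given (configuration, seed).  A master seed
spawns per-subject child seeds with :class:`numpy.random.SeedSequence`, in
subject order (CN block first, then MCI), so the first *k* CN subjects of a
larger cohort are identical to a cohort generated with fewer CN subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as sps

from .calibration import (
    GROUPS,
    calibration_digest,
    default_calibration,
    get_param,
)
from .exceptions import ConstraintError

SAMPLE_RATE_HZ = 250.0
DT_MS = 1000.0 / SAMPLE_RATE_HZ  # 4 ms

STANDARD_TONE_HZ = 750.0
TARGET_TONE_HZ = 2000.0

N_TARGET_DEFAULT = 64
N_STANDARD_DEFAULT = 256
ISI_RANGE_DEFAULT = (900.0, 1100.0)

#: fixed width (SD, ms) of the early negative component; not a fitted quantity
N100_WIDTH_MS = 16.0

#: response latencies outside this window are re-drawn during simulation so a
#: generated press stays attributable to its own stimulus
RESPONSE_WINDOW_MS = (100.0, 1000.0)

ALPHA_FREQ_HZ = 10.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusEvent:
    """One tone presentation. ``kind`` determines the tone frequency."""

    onset_ms: float
    kind: str  # "standard" | "target"
    tone_frequency_hz: float

    def __post_init__(self):
        expected = TARGET_TONE_HZ if self.kind == "target" else STANDARD_TONE_HZ
        if self.kind not in ("standard", "target"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.tone_frequency_hz != expected:
            raise ValueError(
                f"{self.kind} stimulus must be {expected} Hz, got {self.tone_frequency_hz}"
            )


@dataclass(frozen=True)
class ResponseEvent:
    """One key press, in ms from session start."""

    press_time_ms: float


@dataclass
class SubjectParams:
    """Latent per-subject parameters driving one simulated session."""

    group: str
    p300_latency_ms: float
    p300_width_ms: float
    p300_amplitude_uv: float
    n100_amplitude_uv: float
    n100_latency_ms: float
    hit_rate: float
    commission_rate: float
    rt_mu_ms: float
    rt_sigma_ms: float
    rt_tau_ms: float
    noise_sd_uv: float
    alpha_power: float
    age_years: float
    sex: str  # "female" | "male"
    education_years: float
    mmse: float
    snsb_attention: float
    snsb_language: float
    snsb_visuospatial: float
    snsb_memory: float
    snsb_frontal: float

    def __post_init__(self):
        if not 0.0 <= self.hit_rate <= 1.0:
            raise ValueError("hit_rate must lie in [0, 1]")
        if not 0.0 <= self.commission_rate <= 1.0:
            raise ValueError("commission_rate must lie in [0, 1]")
        if self.p300_width_ms <= 0 or self.rt_sigma_ms <= 0 or self.rt_tau_ms < 0:
            raise ValueError("width/sigma must be positive, tau non-negative")


@dataclass
class Subject:
    """Demographic and neuropsychological record of one participant."""

    subject_id: str
    group: str
    age_years: float
    sex: str
    education_years: float
    mmse: float
    snsb_attention: float
    snsb_language: float
    snsb_visuospatial: float
    snsb_memory: float
    snsb_frontal: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SessionRecording:
    """Two-channel prefrontal EEG plus its stimulus/response event log."""

    subject_id: str
    sample_rate: float
    fp1: np.ndarray
    fp2: np.ndarray
    stimuli: list[StimulusEvent]
    responses: list[ResponseEvent]

    def __post_init__(self):
        if len(self.fp1) != len(self.fp2):
            raise ValueError("Fp1 and Fp2 must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.fp1)

    @property
    def duration_ms(self) -> float:
        return self.n_samples * 1000.0 / self.sample_rate


@dataclass
class CohortBundle:
    """All sessions of one simulated cohort, plus the generating digest."""

    subjects: list[tuple[Subject, SessionRecording]] = field(default_factory=list)
    config_digest: str = ""

    def __post_init__(self):
        ids = [s.subject_id for s, _ in self.subjects]
        if len(ids) != len(set(ids)):
            raise ValueError("subject_ids must be unique")

    def __len__(self) -> int:
        return len(self.subjects)


# ---------------------------------------------------------------------------
# stimulus sequences
# ---------------------------------------------------------------------------

def generate_stimulus_sequence(
    n_target: int,
    n_standard: int,
    isi_range_ms: tuple[float, float] = ISI_RANGE_DEFAULT,
    seed=None,
    *,
    no_consecutive_targets: bool = True,
    start_ms: float = 1000.0,
    quantize_ms: float | None = DT_MS,
) -> list[StimulusEvent]:
    """Randomized oddball sequence of ``n_target`` rare and ``n_standard``
    frequent tones with uniformly drawn inter-stimulus onset intervals.

    With ``no_consecutive_targets`` (standard oddball practice) the target
    positions are drawn uniformly from the arrangements in which no two
    targets are adjacent, by choosing target slots among the ``n_standard+1``
    gaps around the standards.

    Onsets are snapped to the EEG sample grid (``quantize_ms``, default one
    sample period), the way a trigger locked to the acquisition clock fires;
    pass ``None`` to keep continuous onsets.
    """
    if n_target < 0 or n_standard < 0:
        raise ConstraintError("stimulus counts must be non-negative")
    lo, hi = float(isi_range_ms[0]), float(isi_range_ms[1])
    if lo <= 0 or hi < lo:
        raise ConstraintError("isi_range_ms must be positive with low <= high")
    rng = np.random.default_rng(seed)

    n = n_target + n_standard
    if n == 0:
        return []
    if no_consecutive_targets:
        if n_target > n_standard + 1:
            raise ConstraintError(
                f"cannot place {n_target} targets among {n_standard} standards "
                "without consecutive targets"
            )
        gaps = np.sort(rng.choice(n_standard + 1, size=n_target, replace=False))
        kinds = []
        gi = 0
        for slot in range(n_standard + 1):
            while gi < n_target and gaps[gi] == slot:
                kinds.append("target")
                gi += 1
            if slot < n_standard:
                kinds.append("standard")
    else:
        kinds = ["target"] * n_target + ["standard"] * n_standard
        rng.shuffle(kinds)

    if hi == lo:
        isis = np.full(n - 1, lo)
    else:
        isis = rng.uniform(lo, hi, size=n - 1)
    onsets = start_ms + np.concatenate(([0.0], np.cumsum(isis)))
    if quantize_ms:
        onsets = np.round(onsets / quantize_ms) * quantize_ms

    tone = {"standard": STANDARD_TONE_HZ, "target": TARGET_TONE_HZ}
    return [
        StimulusEvent(onset_ms=float(t), kind=k, tone_frequency_hz=tone[k])
        for t, k in zip(onsets, kinds)
    ]


# ---------------------------------------------------------------------------
# subject parameters
# ---------------------------------------------------------------------------

def truncnorm_mean(mean: float, sd: float, low=None, high=None) -> float:
    """Analytic mean of the truncated normal used for a calibration entry."""
    if sd == 0:
        return mean
    a = -np.inf if low is None else (low - mean) / sd
    b = np.inf if high is None else (high - mean) / sd
    return float(sps.truncnorm.mean(a, b, loc=mean, scale=sd))


def _draw_truncnorm(rng: np.random.Generator, spec: dict) -> float:
    mean, sd = spec["mean"], spec["sd"]
    if sd == 0:
        return float(mean)
    a = -np.inf if spec.get("low") is None else (spec["low"] - mean) / sd
    b = np.inf if spec.get("high") is None else (spec["high"] - mean) / sd
    # inverse-CDF draw so a single uniform stream drives everything
    return float(sps.truncnorm.ppf(rng.uniform(), a, b, loc=mean, scale=sd))


_PARAM_ORDER = (
    "p300_latency_ms", "p300_width_ms", "p300_amplitude_uv",
    "n100_amplitude_uv", "n100_latency_ms",
    "hit_rate", "commission_rate",
    "rt_mu_ms", "rt_sigma_ms", "rt_tau_ms",
    "noise_sd_uv", "alpha_power",
    "age_years", "education_years", "mmse",
    "snsb_attention", "snsb_language", "snsb_visuospatial",
    "snsb_memory", "snsb_frontal",
)


def simulate_subject_params(group: str, config: dict | None = None, seed=None) -> SubjectParams:
    """Draw one subject's latent parameters from the calibration table."""
    if group not in GROUPS:
        raise ConstraintError(f"group must be one of {GROUPS}, got {group!r}")
    table = config if config is not None else default_calibration()
    rng = np.random.default_rng(seed)
    values = {
        name: _draw_truncnorm(rng, get_param(table, group, name))
        for name in _PARAM_ORDER
    }
    sex = "male" if rng.uniform() < table[group]["male_p"] else "female"
    return SubjectParams(group=group, sex=sex, **values)


# ---------------------------------------------------------------------------
# session synthesis
# ---------------------------------------------------------------------------

def moving_average_gain(sigma_ms: float, taps: int = 9, dt_ms: float = DT_MS) -> float:
    """Peak attenuation a centered ``taps``-point moving average applies to a
    Gaussian bump of SD ``sigma_ms`` sampled every ``dt_ms``."""
    half = taps // 2
    ks = np.arange(-half, half + 1) * dt_ms
    return float(np.exp(-(ks ** 2) / (2.0 * sigma_ms ** 2)).sum() / taps)


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f (pink) noise of length ``n`` via spectral shaping."""
    if n == 0:
        return np.zeros(0)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0  # no DC drift
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _add_gaussian_bump(signal: np.ndarray, center_ms: float, sigma_ms: float,
                       amplitude_uv: float, sample_rate: float) -> None:
    """Add an ``amplitude * exp(-(t-center)^2 / 2 sigma^2)`` bump in place."""
    dt = 1000.0 / sample_rate
    lo = max(0, int(math.floor((center_ms - 5 * sigma_ms) / dt)))
    hi = min(len(signal), int(math.ceil((center_ms + 5 * sigma_ms) / dt)) + 1)
    if hi <= lo:
        return
    t = np.arange(lo, hi) * dt
    signal[lo:hi] += amplitude_uv * np.exp(-((t - center_ms) ** 2) / (2 * sigma_ms ** 2))


def _draw_rt(rng: np.random.Generator, params: SubjectParams) -> float:
    """Ex-Gaussian response latency, re-drawn into the attributable window."""
    lo, hi = RESPONSE_WINDOW_MS
    for _ in range(100):
        rt = params.rt_mu_ms + params.rt_sigma_ms * rng.standard_normal()
        if params.rt_tau_ms > 0:
            rt += rng.exponential(params.rt_tau_ms)
        if lo < rt < hi:
            return rt
    return float(np.clip(rt, lo + 1.0, hi - 1.0))


def synthesize_session(
    stimuli: list[StimulusEvent],
    params: SubjectParams,
    seed=None,
    *,
    subject_id: str = "sim",
    sample_rate: float = SAMPLE_RATE_HZ,
    tail_ms: float = 1000.0,
    smoothing_taps: int = 9,
) -> SessionRecording:
    """Render one subject's two-channel recording plus response log.

    Each channel is pink background noise (SD ``noise_sd_uv``) plus an
    alpha-band sinusoid, with the evoked components added identically to both
    channels: a negative N100 Gaussian for every stimulus and a positive P300
    Gaussian for every target.  The P300 amplitude parameter is defined as the
    peak the standard measurement pipeline reads off in the noiseless case, so
    the injected raw amplitude is pre-divided by the analytic moving-average
    gain for the component's width (the pipeline's mandatory smoothing would
    otherwise shave a few percent off every injected peak).
    """
    if not stimuli:
        raise ConstraintError("stimuli must be nonempty")
    rng = np.random.default_rng(seed)
    dt = 1000.0 / sample_rate
    last_onset = stimuli[-1].onset_ms
    n_samples = int(math.ceil((last_onset + tail_ms) / dt)) + 1

    evoked = np.zeros(n_samples)
    p300_raw = params.p300_amplitude_uv / moving_average_gain(
        params.p300_width_ms, smoothing_taps, dt
    )
    for ev in stimuli:
        _add_gaussian_bump(
            evoked, ev.onset_ms + params.n100_latency_ms, N100_WIDTH_MS,
            -params.n100_amplitude_uv, sample_rate,
        )
        if ev.kind == "target":
            _add_gaussian_bump(
                evoked, ev.onset_ms + params.p300_latency_ms,
                params.p300_width_ms, p300_raw, sample_rate,
            )

    t_s = np.arange(n_samples) * dt / 1000.0
    channels = []
    for _ in range(2):
        chan = evoked.copy()
        if params.noise_sd_uv > 0:
            chan += params.noise_sd_uv * pink_noise(n_samples, rng)
        if params.alpha_power > 0:
            phase = rng.uniform(0, 2 * np.pi)
            chan += params.alpha_power * np.sin(2 * np.pi * ALPHA_FREQ_HZ * t_s + phase)
        channels.append(chan)

    presses: list[float] = []
    for ev in stimuli:
        p = params.hit_rate if ev.kind == "target" else params.commission_rate
        if rng.uniform() < p:
            presses.append(ev.onset_ms + _draw_rt(rng, params))
    presses.sort()
    for i in range(1, len(presses)):  # strictly increasing press times
        if presses[i] <= presses[i - 1]:
            presses[i] = presses[i - 1] + 1e-3

    return SessionRecording(
        subject_id=subject_id,
        sample_rate=sample_rate,
        fp1=channels[0],
        fp2=channels[1],
        stimuli=list(stimuli),
        responses=[ResponseEvent(p) for p in presses],
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def subject_from_params(subject_id: str, params: SubjectParams) -> Subject:
    return Subject(
        subject_id=subject_id,
        group=params.group,
        age_years=params.age_years,
        sex=params.sex,
        education_years=params.education_years,
        mmse=params.mmse,
        snsb_attention=params.snsb_attention,
        snsb_language=params.snsb_language,
        snsb_visuospatial=params.snsb_visuospatial,
        snsb_memory=params.snsb_memory,
        snsb_frontal=params.snsb_frontal,
    )


def generate_cohort(
    n_cn: int,
    n_mci: int,
    config: dict | None = None,
    seed: int | None = None,
    *,
    n_target: int = N_TARGET_DEFAULT,
    n_standard: int = N_STANDARD_DEFAULT,
    isi_range_ms: tuple[float, float] = ISI_RANGE_DEFAULT,
) -> CohortBundle:
    """Generate ``n_cn`` CN and ``n_mci`` MCI sessions with derived seeds.

    Child seed *i* (CN block first, then MCI) is ``SeedSequence(seed).spawn``'s
    *i*-th child, each further split into (params, sequence, session) streams,
    so cohorts are reproducible under subsetting of the leading subjects.
    """
    if n_cn < 0 or n_mci < 0:
        raise ConstraintError("cohort sizes must be non-negative")
    table = config if config is not None else default_calibration()
    master = np.random.SeedSequence(seed)
    children = master.spawn(n_cn + n_mci)

    labels = [("CN", i + 1) for i in range(n_cn)] + [("MCI", i + 1) for i in range(n_mci)]
    subjects: list[tuple[Subject, SessionRecording]] = []
    for child, (group, idx) in zip(children, labels):
        s_params, s_seq, s_sess = child.spawn(3)
        params = simulate_subject_params(group, table, seed=s_params)
        stimuli = generate_stimulus_sequence(
            n_target, n_standard, isi_range_ms, seed=s_seq
        )
        sid = f"{group}{idx:03d}"
        rec = synthesize_session(stimuli, params, seed=s_sess, subject_id=sid)
        subjects.append((subject_from_params(sid, params), rec))

    digest = calibration_digest(table, seed)
    return CohortBundle(subjects=subjects, config_digest=digest)
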