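"""Synthetic test-retest fNIRS study generator.

Forward model
-------------
Each session is simulated at the hemoglobin-concentration level and
mapped to raw dual-wavelength intensities through the same decadic
Beer-Lambert relation the analysis inverts:

* an evoked cortical response (gamma HRF convolved with the stimulus
  boxcar) present only in long channels, spatially attenuated by a
  Gaussian kernel of the distance between the (displaced) channel
  midpoint and the activation focus;
* a superficial/systemic component shared by all channels including the
  short-separation ones: cardiac pulsation at the session heart rate,
  respiration (~0.25 Hz), Mayer waves (~0.1 Hz), and slow drifts, each
  with small per-channel gain and phase variation;
* optional motion artifacts (brief spikes and persistent baseline
  shifts) added in optical density;
* multiplicative white measurement noise on the intensities.

Session-to-session probe displacement models the placement error of the
two positioning conditions: a small scale for anatomically guided
placement and a larger one for the standard head-measurement approach.
Displacement is the only difference between the conditions, encoding the
hypothesis that repositioning error, not physiology alone, drives
test-retest variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .extinction import extinction_matrix
from .probe import ProbeLayout, make_probe

__all__ = [
    "StimSchedule", "PhysioReading", "GroundTruth", "RawRecording",
    "EvokedSpec", "PhysioParams", "NoiseParams", "StudyDesign",
    "make_stim_schedule", "simulate_session", "simulate_study",
]

DPF = 6.0  # differential pathlength factor, both wavelengths


@dataclass(frozen=True)
class StimSchedule:
    """Block-design stimulus timing."""

    onsets: np.ndarray     # s
    duration: float        # s, common to all blocks
    total_duration: float  # s, length of the recording

    @property
    def n_blocks(self) -> int:
        return len(self.onsets)

    def boxcar(self, n_samples: int, fs: float) -> np.ndarray:
        t = np.arange(n_samples) / fs
        box = np.zeros(n_samples)
        for on in self.onsets:
            box[(t >= on) & (t < on + self.duration)] = 1.0
        return box


@dataclass(frozen=True)
class PhysioReading:
    """Sphygmomanometer readings taken before and after a session."""

    hr_pre: float
    hr_post: float
    map_pre: float
    map_post: float

    @property
    def hr(self) -> float:
        return 0.5 * (self.hr_pre + self.hr_post)

    @property
    def map(self) -> float:
        return 0.5 * (self.map_pre + self.map_post)


@dataclass
class GroundTruth:
    """True activation state actually applied to one simulated session."""

    active: np.ndarray          # bool per channel
    amp_hbo: np.ndarray         # uM at HRF peak, per channel
    amp_hbr: np.ndarray         # uM at HRF peak, per channel
    focus: tuple[float, float]  # cm, scalp plane
    displacement: np.ndarray    # (2,) cm, probe shift this session


@dataclass
class RawRecording:
    """Raw dual-wavelength intensity recording plus acquisition context."""

    intensity: np.ndarray       # (n_channels, 2, n_times), > 0
    fs: float
    probe: ProbeLayout
    schedule: StimSchedule
    meta: dict = field(default_factory=dict)
    physio: PhysioReading | None = None
    ground_truth: GroundTruth | None = None

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_times(self) -> int:
        return self.intensity.shape[2]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_times) / self.fs


@dataclass(frozen=True)
class EvokedSpec:
    """Ground-truth evoked response specification."""

    amp_hbo: float = 0.8       # uM at HRF peak in the focus channel
    amp_hbr: float = -0.3      # uM
    focus: tuple[float, float] | None = None  # default: navigated-ROI centre
    kernel_scale: float = 1.0  # cm, Gaussian spatial attenuation
    active_weight: float = 0.25  # channels with kernel weight >= this are "truly active"
    hrf_peak: float = 6.0      # s
    hrf_fwhm: float = 5.2      # s
    session_amp_sd: float = 0.3  # SD of the session-level log amplitude gain


@dataclass(frozen=True)
class PhysioParams:
    """Superficial/systemic signal model (HbO amplitudes in uM).

    Each oscillatory component contributes ``amp * gain_c * sin(2 pi f t
    + phase + jitter_c)`` to superficial HbO, and the same series scaled
    by its HbR coupling ratio to superficial HbR.
    """

    cardiac_amp: float = 0.20
    cardiac_freq: float | None = None   # Hz; None -> session HR / 60
    cardiac_hbr_ratio: float = 0.10
    resp_amp: float = 0.10
    resp_freq: float = 0.25
    resp_hbr_ratio: float = -0.20
    mayer_amp: float = 0.15
    mayer_freq: float = 0.10
    mayer_hbr_ratio: float = -0.30
    drift_amp: float = 0.30
    drift_hbr_ratio: float = 0.40
    gain_sd: float = 0.20               # per-channel gain spread
    phase_jitter: float = 0.30          # rad, per-channel phase spread
    # cortical background hemodynamics: slow colored noise that is
    # channel-specific, hence NOT removable by short-channel regression
    background_hbo: float = 0.30        # uM SD per long channel
    background_hbr: float = 0.10        # uM SD, independent HbR part
    background_ratio: float = -0.4      # HbR coupling to the HbO background
    background_tau: float = 3.0         # s, AR(1) correlation time


@dataclass(frozen=True)
class NoiseParams:
    """Measurement noise and motion-artifact model."""

    intensity_noise: float = 0.005   # multiplicative white noise SD
    spike_rate: float = 0.5          # artifacts per minute, over the whole probe
    spike_amp: float = 10.0          # multiples of the channel OD SD
    spike_dur: tuple[float, float] = (0.2, 0.5)  # s
    shift_prob: float = 0.2          # per-session probability of a baseline shift
    shift_amp: float = 8.0           # multiples of the channel OD SD
    bad_channel_prob: float = 0.0    # probability a channel is low-SNR
    bad_channel_noise: float = 0.2   # intensity noise SD for bad channels


@dataclass(frozen=True)
class StudyDesign:
    """A test-retest study arm: subjects x sessions under one condition."""

    n_subjects: int = 5
    n_days: int = 3
    extra_same_day: int = 0      # extra sessions on day 1 (afternoon/evening)
    condition: str = "standard"  # "standard" | "guided"
    displacement_scale: float | None = None  # cm; None -> per-condition default
    layout: str = "default"
    n_blocks: int = 30
    stim_dur: float = 2.0
    rest_range: tuple[float, float] = (10.0, 20.0)
    fs: float = 8.9
    evoked: EvokedSpec = EvokedSpec()
    physio: PhysioParams = PhysioParams()
    noise: NoiseParams = NoiseParams()
    hr_base_mean: float = 70.0   # bpm
    hr_base_sd: float = 5.0
    map_base_mean: float = 90.0  # mmHg
    map_base_sd: float = 7.0
    day_sd_hr: float = 3.5       # across-day session-to-session spread
    day_sd_map: float = 3.5
    tod_factor: float = 2.0      # time-of-day spread = tod_factor * day spread
    reading_sd: float = 1.0      # pre/post reading noise

# Placement-error scales (cm).  Guided placement keeps optodes within the
# 6 mm guidance spheres; the standard tape-measure procedure has no such
# bound and its scale is a modelling choice, not a measured value.
CONDITION_DISPLACEMENT = {"guided": 0.3, "standard": 1.5}


def make_stim_schedule(
    n_blocks: int = 30,
    stim_dur: float = 2.0,
    rest_min: float = 10.0,
    rest_max: float = 20.0,
    seed: int | np.random.SeedSequence = 0,
    tail: float = 25.0,
) -> StimSchedule:
    """Randomized block design: fixed stimulation, jittered rest.

    Rest intervals are drawn uniformly from [rest_min, rest_max] so that
    the task never synchronizes with periodic physiology (Mayer waves in
    particular).  ``tail`` seconds of rest are appended after the last
    block so the final hemodynamic response is fully sampled.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if stim_dur <= 0 or rest_min < 0 or rest_max < 0:
        raise ValueError("durations must be positive")
    if rest_min > rest_max:
        raise ValueError("rest_min must be <= rest_max")
    rng = np.random.default_rng(seed)
    rests = rng.uniform(rest_min, rest_max, size=n_blocks)
    onsets = np.empty(n_blocks)
    t = rests[0]
    for i in range(n_blocks):
        onsets[i] = t
        t += stim_dur + (rests[i + 1] if i + 1 < n_blocks else tail)
    return StimSchedule(onsets=onsets, duration=stim_dur, total_duration=t)


def _gauss_kernel(dist: np.ndarray, scale: float) -> np.ndarray:
    return np.exp(-0.5 * (dist / scale) ** 2)


def _drift(rng: np.random.Generator, t: np.ndarray, amp: float) -> np.ndarray:
    """Slow drift: three low-frequency sinusoids plus a linear trend."""
    out = np.zeros_like(t)
    for f in rng.uniform(0.008, 0.03, size=3):
        out += np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    out += rng.uniform(-1, 1) * (t / t[-1] if t[-1] > 0 else t)
    rms = np.sqrt(np.mean(out ** 2))
    return amp * out / rms if rms > 0 else out


def simulate_session(
    probe: ProbeLayout,
    schedule: StimSchedule,
    truth: EvokedSpec = EvokedSpec(),
    physio_params: PhysioParams = PhysioParams(),
    noise_params: NoiseParams = NoiseParams(),
    displacement: np.ndarray | tuple[float, float] = (0.0, 0.0),
    seed: int | np.random.SeedSequence = 0,
    fs: float = 8.9,
    physio_reading: PhysioReading | None = None,
    meta: dict | None = None,
    baseline_intensity: float = 1.0e6,
) -> RawRecording:
    """Simulate one session's raw intensities for every probe channel."""
    from .glm import gamma_hrf  # local import to avoid a cycle at import time

    if baseline_intensity <= 0:
        raise ValueError("baseline intensity must be positive")
    displacement = np.asarray(displacement, dtype=float)
    if not np.all(np.isfinite(displacement)):
        raise ValueError("displacement must be finite")
    rng = np.random.default_rng(seed)

    n_ch = probe.n_channels
    n_t = int(np.ceil(schedule.total_duration * fs))
    t = np.arange(n_t) / fs

    if physio_reading is None:
        hr = rng.normal(70.0, 5.0)
        mp = rng.normal(90.0, 7.0)
        physio_reading = PhysioReading(hr, hr, mp, mp)

    # --- evoked cortical component (long channels only) -----------------
    focus = truth.focus
    if focus is None:
        nav = probe.rois.get("navigated")
        mids_nav = probe.midpoints[nav] if nav else probe.midpoints
        focus = tuple(np.mean(mids_nav, axis=0))
    mids = probe.midpoints + displacement
    dist = np.hypot(mids[:, 0] - focus[0], mids[:, 1] - focus[1])
    weight = _gauss_kernel(dist, truth.kernel_scale)
    is_short = np.array([c.is_short for c in probe.channels])
    weight[is_short] = 0.0

    box = schedule.boxcar(n_t, fs)
    kern = gamma_hrf(np.arange(0, 30.0, 1 / fs), peak_time=truth.hrf_peak,
                     fwhm=truth.hrf_fwhm)
    evoked = np.convolve(box, kern)[:n_t]
    pk = evoked.max()
    if pk > 0:
        evoked = evoked / pk  # unit peak: amplitudes are uM at response peak

    sess_gain = (np.exp(truth.session_amp_sd * rng.standard_normal())
                 if truth.session_amp_sd > 0 else 1.0)
    amp_hbo = truth.amp_hbo * weight * sess_gain
    amp_hbr = truth.amp_hbr * weight * sess_gain
    c_hbo = amp_hbo[:, None] * evoked[None, :]
    c_hbr = amp_hbr[:, None] * evoked[None, :]

    # --- superficial/systemic component (all channels) ------------------
    pp = physio_params
    f_card = pp.cardiac_freq if pp.cardiac_freq is not None else physio_reading.hr / 60.0
    comps = [
        (pp.cardiac_amp, f_card, pp.cardiac_hbr_ratio),
        (pp.resp_amp, pp.resp_freq, pp.resp_hbr_ratio),
        (pp.mayer_amp, pp.mayer_freq, pp.mayer_hbr_ratio),
    ]
    for amp, freq, ratio in comps:
        if amp == 0.0:
            continue
        phase = rng.uniform(0, 2 * np.pi)
        gains = 1.0 + pp.gain_sd * rng.standard_normal(n_ch)
        jit = pp.phase_jitter * rng.standard_normal(n_ch)
        wave = np.sin(2 * np.pi * freq * t[None, :] + phase + jit[:, None])
        c_hbo += amp * gains[:, None] * wave
        c_hbr += amp * ratio * gains[:, None] * wave
    if pp.drift_amp > 0:
        base = _drift(rng, t, pp.drift_amp)
        gains = 1.0 + pp.gain_sd * rng.standard_normal(n_ch)
        c_hbo += gains[:, None] * base[None, :]
        c_hbr += pp.drift_hbr_ratio * gains[:, None] * base[None, :]

    # cortical background hemodynamics: independent AR(1) noise per long
    # channel (short channels see scalp only, so they are excluded)
    if pp.background_hbo > 0 and n_t > 1:
        from scipy.signal import lfilter
        phi_b = np.exp(-1.0 / (fs * pp.background_tau))
        long_mask = ~is_short

        def _ar1(shape):
            e = rng.standard_normal(shape)
            x = lfilter([1.0], [1.0, -phi_b], e, axis=-1)
            sd = x.std(axis=-1, keepdims=True)
            sd[sd == 0] = 1.0
            return x / sd

        bg = _ar1((int(long_mask.sum()), n_t)) * pp.background_hbo
        c_hbo[long_mask] += bg
        c_hbr[long_mask] += pp.background_ratio * bg
        if pp.background_hbr > 0:
            c_hbr[long_mask] += _ar1((int(long_mask.sum()), n_t)) * pp.background_hbr

    # --- concentrations -> OD -> intensity ------------------------------
    ext = extinction_matrix(probe.wavelengths)  # (2 wl, 2 chrom), per uM per cm
    seps = probe.separations
    conc = np.stack([c_hbo, c_hbr], axis=1)     # (ch, chrom, t)
    od = np.einsum("wc,nct->nwt", ext, conc) * (seps[:, None, None] * DPF)

    # motion artifacts, in OD
    np_ = noise_params
    od_sd = od.std(axis=2, keepdims=True)
    duration_min = schedule.total_duration / 60.0
    n_spikes = rng.poisson(np_.spike_rate * duration_min)
    for _ in range(n_spikes):
        ch = rng.integers(n_ch)
        dur = rng.uniform(*np_.spike_dur)
        w = max(2, int(dur * fs))
        start = rng.integers(0, max(1, n_t - w))
        bump = np.sin(np.linspace(0, np.pi, w))
        sign = rng.choice([-1.0, 1.0])
        od[ch, :, start:start + w] += (
            sign * np_.spike_amp * od_sd[ch, :, 0][:, None] * bump[None, :])
    if rng.uniform() < np_.shift_prob and np_.shift_amp > 0:
        ch = rng.integers(n_ch)
        start = rng.integers(n_t // 4, max(n_t // 4 + 1, 3 * n_t // 4))
        sign = rng.choice([-1.0, 1.0])
        od[ch, :, start:] += sign * np_.shift_amp * od_sd[ch, :, 0][:, None]

    intensity = baseline_intensity * 10.0 ** (-od)
    noise_sd = np.full(n_ch, np_.intensity_noise)
    if np_.bad_channel_prob > 0:
        bad = rng.uniform(size=n_ch) < np_.bad_channel_prob
        noise_sd[bad] = np_.bad_channel_noise
    if np.any(noise_sd > 0):
        mult = 1.0 + noise_sd[:, None, None] * rng.standard_normal(od.shape)
        intensity = intensity * np.clip(mult, 0.05, None)

    gt = GroundTruth(
        active=weight >= truth.active_weight,
        amp_hbo=amp_hbo, amp_hbr=amp_hbr,
        focus=tuple(focus), displacement=displacement,
    )
    return RawRecording(
        intensity=intensity, fs=fs, probe=probe, schedule=schedule,
        meta=dict(meta or {}), physio=physio_reading, ground_truth=gt,
    )


def _session_plan(design: StudyDesign) -> list[tuple[int, str]]:
    plan = [(d, "morning") for d in range(1, design.n_days + 1)]
    tods = ["afternoon", "evening"]
    for k in range(design.extra_same_day):
        plan.append((1, tods[k % 2]))
    return plan


def simulate_study(design: StudyDesign, seed: int | np.random.SeedSequence = 0
                   ) -> list[RawRecording]:
    """Simulate every (subject, session) recording of one study arm.

    Time-of-day (circadian) variation of heart rate and arterial
    pressure is larger than day-to-day variation at a fixed time, so
    same-day extra sessions show the larger physiological swings.
    """
    scale = design.displacement_scale
    if scale is None:
        scale = CONDITION_DISPLACEMENT[design.condition]
    if scale < 0:
        raise ValueError("displacement scale must be >= 0")

    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    probe = make_probe(layout=design.layout)
    plan = _session_plan(design)
    recordings: list[RawRecording] = []
    for subj_ss in ss.spawn(design.n_subjects):
        sub_rng = np.random.default_rng(subj_ss)
        subj_id = f"S{len(recordings) // len(plan) + 1:02d}"
        hr_base = sub_rng.normal(design.hr_base_mean, design.hr_base_sd)
        map_base = sub_rng.normal(design.map_base_mean, design.map_base_sd)
        day_hr = sub_rng.normal(0, design.day_sd_hr, size=design.n_days)
        day_map = sub_rng.normal(0, design.day_sd_map, size=design.n_days)
        tod_hr = {"morning": 0.0}
        tod_map = {"morning": 0.0}
        for tod in ("afternoon", "evening"):
            tod_hr[tod] = sub_rng.normal(0, design.tod_factor * design.day_sd_hr)
            tod_map[tod] = sub_rng.normal(0, design.tod_factor * design.day_sd_map)

        for s_idx, (day, tod) in enumerate(plan, start=1):
            sess_ss, sched_ss, disp_ss = subj_ss.spawn(3)[:3]
            rng = np.random.default_rng(disp_ss)
            schedule = make_stim_schedule(
                design.n_blocks, design.stim_dur, *design.rest_range,
                seed=sched_ss)
            # isotropic 2-D placement error; magnitude is Rayleigh(scale)
            disp = rng.normal(0, scale, size=2) if scale > 0 else np.zeros(2)
            hr = hr_base + day_hr[day - 1] + tod_hr[tod]
            mp = map_base + day_map[day - 1] + tod_map[tod]
            reading = PhysioReading(
                hr_pre=hr + rng.normal(0, design.reading_sd),
                hr_post=hr + rng.normal(0, design.reading_sd),
                map_pre=mp + rng.normal(0, design.reading_sd),
                map_post=mp + rng.normal(0, design.reading_sd),
            )
            rec = simulate_session(
                probe, schedule, design.evoked, design.physio, design.noise,
                displacement=disp, seed=sess_ss, fs=design.fs,
                physio_reading=reading,
                meta={
                    "subject": subj_id, "session": f"sess{s_idx}",
                    "condition": design.condition, "day": day,
                    "time_of_day": tod,
                },
            )
            recordings.append(rec)
    return recordings
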