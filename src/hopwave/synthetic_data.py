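"""Synthetic one-leg hop cohorts with known ground truth.

No raw recordings from the study cohort are available, so this module
manufactures trials whose structure mirrors the acquisition protocol:
seven EMG channels at 3000 Hz, vertical ground reaction force on the
same clock, and ankle vertical velocity plus knee flexion at 125 Hz.
Every generated trial carries its constructed phase events (t0-t3) as
ground truth, which makes event detection, normalization and
classification testable end to end.

Signal model
------------
Each muscle fires one or two bursts per hop.  A burst is band-limited
Gaussian noise, spectrally shaped by a Gaussian window around a
muscle-specific centroid frequency, under a Hann envelope of compact
support — so the quiet baseline before movement onset is exactly zero
in the noise-free limit, and onsets are sharp.  60 Hz line interference
and white baseline noise are added on top.  Group differences (the
"ACLR" group relative to "Control") are injected as shifts in burst
amplitude, onset latency and spectral centroid, scaled by a single
``effect_size`` knob and optionally restricted to a subset of muscles
and hop phases; at ``effect_size = 0`` the two groups are statistically
identical.  Group effects apply to both limbs of an ACLR subject
(bilateral adaptation), with an optional extra factor on the surgical
limb.

Randomness: one master seed; every (subject, limb, trial) triple hashes
to its own substream, so any single trial can be regenerated without
replaying the whole cohort.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import fft as _fft

from .errors import ConfigurationError
from .outcomes_stats import SubjectOutcomes
from .signal_io import MUSCLES, TrialRecording

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "CohortData",
    "generate_trial",
    "generate_cohort",
    "generate_outcomes",
]

PHASES = ("take-off", "airborne", "landing")

# burst plan per muscle: (phase, relative center in phase, width s,
# spectral centroid Hz, peak amplitude mV, pinned-to-onset flag)
_BURST_PLANS: dict[str, list[tuple[str, float, float, float, float, bool]]] = {
    "GM": [("take-off", 0.80, 0.35, 125.0, 0.9, False), ("landing", 0.60, 0.18, 125.0, 1.2, False)],
    "GL": [("take-off", 0.80, 0.35, 140.0, 0.8, False), ("landing", 0.60, 0.18, 140.0, 1.1, False)],
    "TA": [("airborne", 0.75, 0.25, 115.0, 0.9, False), ("landing", 0.40, 0.15, 115.0, 0.9, False)],
    "VM": [("take-off", 0.0, 0.45, 95.0, 1.1, True), ("landing", 0.50, 0.20, 95.0, 1.3, False)],
    "RF": [("take-off", 0.0, 0.45, 90.0, 1.0, True), ("landing", 0.50, 0.20, 90.0, 1.1, False)],
    "BF": [("take-off", 0.60, 0.30, 105.0, 0.7, False), ("airborne", 0.50, 0.30, 105.0, 0.9, False)],
    "ST": [("airborne", 0.55, 0.30, 100.0, 0.9, False), ("landing", 0.50, 0.20, 100.0, 0.8, False)],
}

# per unit of effect_size: log amplitude multiplier, latency shift (s),
# spectral centroid shift (Hz), applied to ACLR bursts in scope
_EFFECT_AMP_LOG = 0.45
_EFFECT_LATENCY_S = 0.015
_EFFECT_CENTROID_HZ = 6.0


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort.

    ``n_per_group`` is ``(n_controls, n_aclr)`` (a single int applies to
    both groups).  ``effect_size`` scales all injected group
    differences; ``effect_muscles``/``effect_phases`` of None target
    every muscle/phase.  Amplitudes are millivolts, durations seconds.
    """

    n_per_group: tuple[int, int] | int = (12, 11)
    trials_per_limb: int = 3
    muscles: tuple[str, ...] = MUSCLES
    fs_emg: float = 3000.0
    fs_mocap: float = 125.0
    line_freq: float = 60.0
    line_amplitude: float = 0.05
    noise_sd: float = 0.01
    effect_size: float = 0.0
    effect_muscles: tuple[str, ...] | None = None
    effect_phases: tuple[str, ...] | None = None
    surgical_extra: float = 0.15  # extra effect fraction on the surgical limb
    phase_durations: tuple[float, float, float] = (0.6, 0.35, 0.07)
    baseline_s: float = 0.6
    tail_s: float = 0.25
    duration_jitter: float = 0.06
    subject_jitter: float = 0.3  # scales between-subject parameter spread
    missing_trial_rate: float = 0.0
    hop_distance_fraction: float = 0.65
    girth_worm_slope: float = -20.8
    worm_intercept: float = 15.0
    worm_noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_per_group, int):
            self.n_per_group = (self.n_per_group, self.n_per_group)
        if min(self.n_per_group) < 2:
            raise ConfigurationError("n_per_group must be >= 2 in both groups")
        if any(d <= 0 for d in self.phase_durations):
            raise ConfigurationError("phase_durations must all be positive")
        if not 0 <= self.missing_trial_rate < 1:
            raise ConfigurationError("missing_trial_rate must lie in [0, 1)")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be nonnegative")
        max_carrier = max(p[3] for plans in _BURST_PLANS.values() for p in plans)
        if self.fs_emg <= 2.0 * max_carrier:
            raise ConfigurationError("fs_emg must exceed twice the highest burst carrier")
        if tuple(self.muscles) != MUSCLES:
            raise ConfigurationError(f"muscles must be exactly {MUSCLES}")

    @property
    def clock_ratio(self) -> int:
        return int(round(self.fs_emg / self.fs_mocap))


@dataclass(frozen=True)
class GroundTruth:
    """Constructed phase events of one trial, on the EMG clock."""

    t0: int
    t1: int
    t2: int
    t3: int
    group: str
    limb: str
    subject_id: str = ""
    trial_index: int = 0

    def __post_init__(self) -> None:
        if not self.t0 < self.t1 < self.t2 < self.t3:
            raise ConfigurationError("ground-truth events must be strictly ordered")


@dataclass
class CohortData:
    """A generated cohort: trials with ground truth plus subject outcomes."""

    trials: list  # list[tuple[TrialRecording, GroundTruth]]
    outcomes: list  # list[SubjectOutcomes]
    config: SimulationConfig

    def outcome_table(self) -> pd.DataFrame:
        rows = [vars(o).copy() for o in self.outcomes]
        return pd.DataFrame(rows)


def _trial_rng(config: SimulationConfig, subject_id: str, limb: str, trial_index: int):
    key = (zlib.crc32(f"{subject_id}|{limb}".encode()), trial_index)
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=key))


def _subject_rng(config: SimulationConfig, subject_id: str):
    key = (zlib.crc32(subject_id.encode()), 7777)
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=key))


def _onset_envelope(length: int, attack_n: int) -> np.ndarray:
    """Fast-attack envelope: half-cosine rise, cosine decay; zero at both ends.

    Used for movement-onset bursts so that EMG amplitude departs the
    baseline quickly (tens of milliseconds), as real onsets do.
    """
    a = int(np.clip(attack_n, 2, length // 3))
    rise = 0.5 * (1.0 - np.cos(np.pi * np.arange(a) / a))
    decay = 0.5 * (1.0 + np.cos(np.pi * np.arange(length - a) / (length - a - 1)))
    return np.concatenate([rise, decay])


def _band_limited_burst(rng, n: int, fs: float, centroid: float, sigma_f: float = 25.0):
    """Unit-RMS noise carrier with a Gaussian spectrum around ``centroid``."""
    white = rng.standard_normal(n)
    spec = _fft.rfft(white)
    freqs = _fft.rfftfreq(n, d=1.0 / fs)
    spec *= np.exp(-0.5 * ((freqs - centroid) / sigma_f) ** 2)
    x = _fft.irfft(spec, n)
    rms = x.std()
    return x / rms if rms > 0 else x


def _effect_deltas(config: SimulationConfig, group: str, limb: str, muscle: str, phase: str):
    """(log-amp, latency s, centroid Hz) shifts for one burst."""
    if group != "ACLR" or config.effect_size == 0:
        return 0.0, 0.0, 0.0
    if config.effect_muscles is not None and muscle not in config.effect_muscles:
        return 0.0, 0.0, 0.0
    if config.effect_phases is not None and phase not in config.effect_phases:
        return 0.0, 0.0, 0.0
    scale = config.effect_size * (1.0 + (config.surgical_extra if limb == "index" else 0.0))
    return (_EFFECT_AMP_LOG * scale, _EFFECT_LATENCY_S * scale, _EFFECT_CENTROID_HZ * scale)


def generate_trial(
    config: SimulationConfig,
    group: str,
    limb: str,
    subject_id: str,
    trial_index: int = 0,
) -> tuple[TrialRecording, GroundTruth]:
    """Generate one hop trial plus its ground-truth events.

    ``limb`` accepts ``"surgical"`` as an alias for ``"index"``.  The
    group label enters only through the deterministic effect shifts, so
    at ``effect_size = 0`` the two group labels produce bit-identical
    channels for the same subject/limb/trial substream.
    """
    if group not in ("ACLR", "Control"):
        raise ConfigurationError(f"unknown group label {group!r}")
    if limb == "surgical":
        limb = "index"
    if limb not in ("index", "contralateral"):
        raise ConfigurationError(f"unknown limb label {limb!r}")
    fs, ratio = config.fs_emg, config.clock_ratio
    rng = _trial_rng(config, subject_id, limb, trial_index)
    srng = _subject_rng(config, subject_id)
    jit = config.subject_jitter
    subj_amp = {m: float(np.exp(jit * 0.08 * srng.standard_normal())) for m in MUSCLES}
    subj_lat = {m: float(jit * 0.005 * srng.standard_normal()) for m in MUSCLES}
    subj_cf = {m: float(jit * 3.0 * srng.standard_normal()) for m in MUSCLES}

    # --- timeline (t0 and t1 aligned to the motion-capture grid) ---
    d0, d1, d2 = (
        d * float(np.exp(config.duration_jitter * rng.standard_normal()))
        for d in config.phase_durations
    )
    t0 = ratio * max(2, int(round(config.baseline_s * fs / ratio)))
    t1 = t0 + ratio * max(2, int(round(d0 * fs / ratio)))
    t2 = t1 + max(2 * ratio, int(round(d1 * fs)))
    t3 = t2 + max(2, int(round(d2 * fs)))
    n = ratio * int(np.ceil((t3 + config.tail_s * fs) / ratio))
    n_mocap = n // ratio
    m0, m1, m2 = t0 // ratio, t1 // ratio, t2 // ratio
    phase_bounds = {"take-off": (t0, t1), "airborne": (t1, t2), "landing": (t2, t3)}

    # --- EMG ---
    emg = {}
    for muscle in MUSCLES:
        x = np.zeros(n)
        for phase, rel, width, centroid, amp, pinned in _BURST_PLANS[muscle]:
            d_amp, d_lat, d_cf = _effect_deltas(config, group, limb, muscle, phase)
            a, b = phase_bounds[phase]
            width_s = width * float(np.exp(0.08 * rng.standard_normal()))
            length = max(8, int(round(width_s * fs)))
            amp_mv = (
                amp
                * subj_amp[muscle]
                * float(np.exp(0.15 * rng.standard_normal()))
                * float(np.exp(d_amp))
            )
            cf = centroid + subj_cf[muscle] + 5.0 * rng.standard_normal() + d_cf
            cf = float(np.clip(cf, 40.0, 0.45 * fs))
            if pinned:
                start = t0  # onset bursts anchor the ground-truth movement start
            else:
                center = a + rel * (b - a) + (subj_lat[muscle] + d_lat) * fs
                center += 0.008 * fs * rng.standard_normal()
                start = int(round(center - length / 2))
                start = max(start, t0)  # nothing fires before movement onset
            stop = min(start + length, n)
            if stop - start < 8:
                continue
            carrier = _band_limited_burst(rng, stop - start, fs, cf)
            if pinned:
                env = _onset_envelope(stop - start, int(round(0.03 * fs)))
            else:
                env = np.hanning(stop - start)
            x[start:stop] += amp_mv * env * carrier
        if config.line_amplitude > 0:
            phase0 = rng.uniform(0, 2 * np.pi)
            x += config.line_amplitude * np.sin(
                2 * np.pi * config.line_freq * np.arange(n) / fs + phase0
            )
        if config.noise_sd > 0:
            x += config.noise_sd * rng.standard_normal(n)
        emg[muscle] = x

    # --- vertical ground reaction force (landing only; zero before contact) ---
    vgrf = np.zeros(n)
    peak = 1600.0 + 150.0 * rng.standard_normal()
    peak = float(np.clip(peak, 1000.0, 2400.0))
    vgrf[t2 - 4 : t2 + 1] = np.linspace(12.0, 60.0, 5)  # crosses 50 N exactly at t2
    ramp = np.arange(1, t3 - t2 + 1) / (t3 - t2)
    vgrf[t2 + 1 : t3 + 1] = 60.0 + (peak - 60.0) * 0.5 * (1.0 - np.cos(np.pi * ramp))
    settle_len = min(n - t3 - 1, int(0.12 * fs))
    if settle_len > 0:
        sr = np.arange(1, settle_len + 1) / settle_len
        vgrf[t3 + 1 : t3 + 1 + settle_len] = 700.0 + (peak - 700.0) * 0.5 * (
            1.0 + np.cos(np.pi * sr)
        )
        vgrf[t3 + 1 + settle_len :] = 700.0

    # --- ankle vertical velocity (motion-capture clock) ---
    vz = np.zeros(n_mocap)
    dip = np.arange(m1 - m0 + 1) / (m1 - m0)
    vz[m0 : m1 + 1] = -1.2 * 0.5 * (1.0 - np.cos(np.pi * dip))  # unique minimum at m1
    m_apex = m1 + max(2, int(0.4 * (m2 - m1)))
    rise = np.arange(1, m_apex - m1 + 1) / (m_apex - m1)
    vz[m1 + 1 : m_apex + 1] = -1.2 + 3.4 * 0.5 * (1.0 - np.cos(np.pi * rise))
    fall = np.arange(1, m2 - m_apex + 1) / max(1, m2 - m_apex)
    vz[m_apex + 1 : m2 + 1] = 2.2 - 3.0 * fall
    vz[m2 + 1 :] = 0.0

    # --- knee flexion (motion-capture clock); ramp starts one sample
    # before t0 so the first departure from baseline is at m0 itself ---
    knee = np.full(n_mocap, 5.0)
    k_start = m0 - 1
    flex = np.arange(m1 - k_start + 1) / (m1 - k_start)
    knee[k_start : m1 + 1] = 5.0 + 40.0 * 0.5 * (1.0 - np.cos(np.pi * flex))
    air = np.arange(1, m2 - m1 + 1) / (m2 - m1)
    knee[m1 + 1 : m2 + 1] = 45.0 - 15.0 * air
    land_len = min(n_mocap - m2 - 1, 10)
    if land_len > 0:
        knee[m2 + 1 : m2 + 1 + land_len] = 30.0 + 25.0 * np.arange(1, land_len + 1) / land_len
        knee[m2 + 1 + land_len :] = 55.0

    trial = TrialRecording(
        subject_id=subject_id,
        group=group,
        limb=limb,
        emg=pd.DataFrame(emg),
        vgrf=vgrf,
        ankle_vz=vz,
        knee_flexion=knee,
        fs_emg=fs,
        fs_mocap=config.fs_mocap,
        trial_index=trial_index,
    )
    truth = GroundTruth(
        t0=t0, t1=t1, t2=t2, t3=t3, group=group, limb=limb,
        subject_id=subject_id, trial_index=trial_index,
    )
    return trial, truth


def _simulate_outcomes(config: SimulationConfig, subject_id: str, group: str) -> SubjectOutcomes:
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(zlib.crc32(subject_id.encode()), 4242))
    )
    if group == "ACLR":
        girth = -1.5 + 0.8 * rng.standard_normal()
    else:
        girth = 0.3 * rng.standard_normal()
    girth = round(2.0 * girth) / 2.0  # tape-measure resolution of 0.5 cm
    if group == "ACLR":
        worm = config.worm_intercept + config.girth_worm_slope * girth
        worm += config.worm_noise_sd * rng.standard_normal()
    else:
        worm = 8.0 + 4.0 * rng.standard_normal()
    worm = max(0.0, worm)
    laxity = (0.3 if group == "ACLR" else 0.0) + (2.0 if group == "ACLR" else 0.7) * rng.standard_normal()
    hop = (96.0 if group == "ACLR" else 100.0) + (9.0 if group == "ACLR" else 6.0) * rng.standard_normal()
    hop = float(np.clip(hop, 40.0, 160.0))
    tegner = int(np.clip(round(5.6 + 1.4 * rng.standard_normal()), 0, 10))
    return SubjectOutcomes(
        subject_id=subject_id,
        group=group,
        girth_delta=girth,
        laxity_delta=float(laxity),
        hop_ratio=hop,
        tegner=tegner,
        worms_total=float(worm),
        age=float(np.clip(35.0 + 9.0 * rng.standard_normal(), 18.0, 65.0)),
        bmi=float(np.clip(26.0 + 3.5 * rng.standard_normal(), 17.0, 40.0)),
        follow_up=float(rng.choice([10.0, 12.0, 12.0, 12.0, 15.0])),
    )


def generate_outcomes(config: SimulationConfig) -> list[SubjectOutcomes]:
    """Subject outcomes alone (no signal synthesis) — cheap for statistics work."""
    n_control, n_aclr = config.n_per_group
    subjects = [(f"CTRL{i+1:02d}", "Control") for i in range(n_control)]
    subjects += [(f"ACLR{i+1:02d}", "ACLR") for i in range(n_aclr)]
    return [_simulate_outcomes(config, sid, grp) for sid, grp in subjects]


def generate_cohort(config: SimulationConfig) -> CohortData:
    """Generate a full two-group cohort of trials and subject outcomes.

    Trials are dropped independently with probability
    ``missing_trial_rate`` (from a dedicated substream, so the retained
    trials are identical whether or not others are dropped).
    """
    n_control, n_aclr = config.n_per_group
    subjects = [(f"CTRL{i+1:02d}", "Control") for i in range(n_control)]
    subjects += [(f"ACLR{i+1:02d}", "ACLR") for i in range(n_aclr)]
    trials = []
    outcomes = []
    for subject_id, group in subjects:
        for limb in ("index", "contralateral"):
            for k in range(config.trials_per_limb):
                if config.missing_trial_rate > 0:
                    drop_rng = np.random.default_rng(
                        np.random.SeedSequence(
                            entropy=config.seed,
                            spawn_key=(zlib.crc32(f"{subject_id}|{limb}".encode()), k, 5555),
                        )
                    )
                    if drop_rng.uniform() < config.missing_trial_rate:
                        continue
                trials.append(generate_trial(config, group, limb, subject_id, k))
        outcomes.append(_simulate_outcomes(config, subject_id, group))
    return CohortData(trials=trials, outcomes=outcomes, config=config)
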