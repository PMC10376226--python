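"""Hop-phase event detection and trial segmentation.

A one-leg hop trial is split into three phases by four events, all
reported as sample indices on the EMG clock:

* ``t0`` — movement onset: EMG amplitude and knee flexion both depart
  from their quiet-standing baselines (the later of the two onsets).
* ``t1`` — take-off: minimum vertical ankle velocity before plate
  contact.
* ``t2`` — contact: vertical ground reaction force first exceeds 50 N.
* ``t3`` — peak vertical ground reaction force of the landing transient.

Phases are the half-open intervals [t0, t1), [t1, t2) and the closed
landing interval [t2, t3], so consecutive phases partition the record.

Onset detection (t0) uses a short causal moving-average envelope of the
summed squared raw EMG rather than the wavelet intensity maps: the
wavelet envelopes of the low-frequency bands spread energy over tens of
milliseconds and would blur the onset, while the broadband envelope
keeps it sharp.  The threshold is baseline mean + k_sd * baseline SD,
exceeded for a sustained run (25 ms by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EventNotFoundError, SegmentationError
from .signal_io import TrialRecording

__all__ = ["PhaseEvents", "detect_t0", "detect_t1", "detect_t2", "detect_t3", "segment"]

PHASE_NAMES = ("take-off", "airborne", "landing")


@dataclass(frozen=True)
class PhaseEvents:
    """The four phase-boundary events, on the EMG clock."""

    t0: int
    t1: int
    t2: int
    t3: int

    def __post_init__(self) -> None:
        if not self.t0 < self.t1 < self.t2 < self.t3:
            raise SegmentationError(
                f"events must be strictly ordered t0 < t1 < t2 < t3, "
                f"got ({self.t0}, {self.t1}, {self.t2}, {self.t3})"
            )

    def phase_slice(self, phase: str) -> slice:
        """Sample slice of one named phase (landing includes t3)."""
        if phase == "take-off":
            return slice(self.t0, self.t1)
        if phase == "airborne":
            return slice(self.t1, self.t2)
        if phase == "landing":
            return slice(self.t2, self.t3 + 1)
        raise SegmentationError(f"unknown phase {phase!r}")


def detect_t2(vgrf: np.ndarray, threshold: float = 50.0) -> int:
    """First sample where vGRF rises above ``threshold`` newtons.

    Returns the smallest index i with vgrf[i] > threshold and
    vgrf[i-1] <= threshold; the trial must contain an unloaded interval
    before contact.
    """
    v = np.asarray(vgrf, dtype=float)
    above = v > threshold
    if not above.any():
        raise EventNotFoundError(f"vGRF never exceeds {threshold} N")
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if crossings.size == 0:
        raise EventNotFoundError("vGRF starts above threshold and never crosses upward")
    return int(crossings[0])


def detect_t3(vgrf: np.ndarray, t2: int) -> int:
    """Peak of the landing force transient at or after ``t2``.

    The first local maximum after contact that attains the global
    maximum of the post-contact record.
    """
    v = np.asarray(vgrf, dtype=float)
    if not 0 <= t2 < v.size:
        raise EventNotFoundError("t2 outside the record")
    seg = v[t2:]
    peak = int(np.argmax(seg))  # first occurrence on a plateau
    # the force must come back down after the maximum, else there is no
    # landing transient (monotone or flat tail)
    if not np.any(seg[peak:] < seg[peak]):
        raise EventNotFoundError("vGRF does not fall after its post-contact maximum")
    return t2 + peak


def detect_t1(ankle_vz: np.ndarray, t2_emg: int, clock_ratio: int = 24) -> int:
    """Minimum vertical ankle velocity strictly before contact.

    ``ankle_vz`` is on the motion-capture clock; ``t2_emg`` on the EMG
    clock.  The returned index is mapped back to the EMG clock by the
    integer clock ratio.
    """
    vz = np.asarray(ankle_vz, dtype=float)
    m2 = t2_emg // clock_ratio
    if m2 < 1 or m2 > vz.size:
        raise EventNotFoundError("no pre-contact window on the motion-capture clock")
    window = vz[:m2]
    m1 = int(np.argmin(window))
    return m1 * clock_ratio


def _onset_index(
    series: np.ndarray,
    baseline_n: int,
    k_sd: float,
    min_run: int,
) -> int:
    """First index of a run of >= min_run samples above baseline mean + k_sd*SD."""
    x = np.asarray(series, dtype=float)
    if baseline_n < 2 or baseline_n >= x.size:
        raise EventNotFoundError("no quiet baseline window available")
    base = x[:baseline_n]
    with np.errstate(invalid="ignore"):  # k_sd=inf with zero SD -> nan -> error below
        thr = base.mean() + k_sd * base.std()
    if not np.isfinite(thr):
        raise EventNotFoundError("unreachable onset threshold")
    above = (x > thr).astype(np.int64)
    if min_run > 1:
        window = np.convolve(above, np.ones(min_run, dtype=np.int64), mode="valid")
        starts = np.flatnonzero(window == min_run)
    else:
        starts = np.flatnonzero(above)
    if starts.size == 0:
        raise EventNotFoundError("no sustained departure from baseline found")
    return int(starts[0])


def detect_t0(
    emg_power: np.ndarray,
    knee_flexion: np.ndarray,
    fs_emg: float = 3000.0,
    fs_mocap: float = 125.0,
    baseline_window: float = 0.4,
    k_sd: float = 3.0,
    min_run_s: float = 0.025,
    smooth_s: float = 0.010,
) -> int:
    """Movement onset from EMG power and knee flexion (later of the two).

    ``emg_power`` is an instantaneous broadband power series on the EMG
    clock (e.g. the sum of squared EMG channels); it is smoothed with a
    causal moving average of ``smooth_s`` seconds before thresholding.
    Knee-flexion departure is detected on the motion-capture clock from
    the absolute deviation from the static baseline.
    """
    p = np.asarray(emg_power, dtype=float)
    w = max(1, int(round(smooth_s * fs_emg)))
    env = np.convolve(p, np.ones(w) / w, mode="full")[: p.size]
    emg_onset = _onset_index(
        env,
        baseline_n=int(round(baseline_window * fs_emg)),
        k_sd=k_sd,
        min_run=max(1, int(round(min_run_s * fs_emg))),
    )
    knee = np.asarray(knee_flexion, dtype=float)
    base_n = int(round(baseline_window * fs_mocap))
    dev = np.abs(knee - knee[:base_n].mean())
    knee_onset_mocap = _onset_index(dev, baseline_n=base_n, k_sd=k_sd, min_run=2)
    ratio = int(round(fs_emg / fs_mocap))
    return max(emg_onset, knee_onset_mocap * ratio)


def segment(
    trial: TrialRecording,
    contact_threshold: float = 50.0,
    baseline_window: float = 0.4,
    k_sd: float = 3.0,
) -> PhaseEvents:
    """Detect all four events of one trial and validate their ordering."""
    t2 = detect_t2(trial.vgrf, contact_threshold)
    t3 = detect_t3(trial.vgrf, t2)
    t1 = detect_t1(trial.ankle_vz, t2, trial.clock_ratio)
    power = (trial.emg.to_numpy(dtype=float) ** 2).sum(axis=1)
    t0 = detect_t0(
        power,
        trial.knee_flexion,
        fs_emg=trial.fs_emg,
        fs_mocap=trial.fs_mocap,
        baseline_window=baseline_window,
        k_sd=k_sd,
    )
    return PhaseEvents(t0=t0, t1=t1, t2=t2, t3=t3)
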