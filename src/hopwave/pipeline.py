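"""End-to-end glue: raw trial -> conditioned -> wavelet -> normalized pattern.

Thin composition of the stage modules, used by the command-line
interface, the test suite and the acceptance script.  Nothing here adds
behavior beyond wiring the stages together in the canonical order:
segment on the raw channels, condition the EMG, compute per-muscle
wavelet intensity, then time-warp and z-normalize.
"""

from __future__ import annotations


from .conditioning import FilterSpec, condition_signal
from .patterning import FRAMES_PER_PHASE, NormalizedPattern, normalize_pattern
from .segmentation import PhaseEvents, segment
from .signal_io import MUSCLES, TrialRecording
from .synthetic_data import CohortData
from .wavelet import WaveletBank, build_filter_bank, intensity

__all__ = ["process_trial", "process_cohort"]


def process_trial(
    trial: TrialRecording,
    bank: WaveletBank | None = None,
    filter_spec: FilterSpec = FilterSpec(),
    events: PhaseEvents | None = None,
    muscles=MUSCLES,
    frames_per_phase: int = FRAMES_PER_PHASE,
) -> tuple[list[NormalizedPattern], PhaseEvents]:
    """All normalized per-muscle patterns of one trial (plus its events).

    Events are detected from the raw channels unless supplied; EMG is
    conditioned before the wavelet transform.
    """
    if bank is None:
        bank = build_filter_bank()
    if events is None:
        events = segment(trial)
    conditioned = condition_signal(
        trial.emg[list(muscles)].to_numpy().T, trial.fs_emg, filter_spec
    )
    patterns = []
    for row, muscle in enumerate(muscles):
        imap = intensity(conditioned[row], bank, trial.fs_emg, muscle=muscle)
        patterns.append(
            normalize_pattern(
                imap,
                events,
                frames_per_phase=frames_per_phase,
                subject_id=trial.subject_id,
                group=trial.group,
                limb=trial.limb,
                trial_index=trial.trial_index,
            )
        )
    return patterns, events


def process_cohort(
    cohort: CohortData,
    bank: WaveletBank | None = None,
    filter_spec: FilterSpec = FilterSpec(),
    muscles=MUSCLES,
    use_ground_truth_events: bool = False,
) -> list[NormalizedPattern]:
    """Flat list of normalized patterns for every trial in a cohort."""
    if bank is None:
        bank = build_filter_bank()
    patterns = []
    for trial, truth in cohort.trials:
        events = (
            PhaseEvents(truth.t0, truth.t1, truth.t2, truth.t3)
            if use_ground_truth_events
            else None
        )
        pats, _ = process_trial(
            trial, bank=bank, filter_spec=filter_spec, events=events, muscles=muscles
        )
        patterns.extend(pats)
    return patterns
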