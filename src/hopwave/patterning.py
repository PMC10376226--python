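"""Phase-wise time normalization and intensity normalization of wavelet maps.

Trials differ in duration, so each hop phase is resampled to a fixed
number of frames (100 per phase, 300 total) by linear interpolation over
normalized phase time.  To remove between-subject baseline differences
in EMG intensity, each wavelet band of the warped map is z-normalized
(mean subtracted, divided by the SD) over the 300 frames.  The pipeline
intensity -> time_normalize -> z_normalize is therefore invariant to an
overall gain on the raw EMG.  Normalized patterns can be averaged across
trials and subjects for inspection and exported as numeric maps with a
display-only [0, 1] rescale.

Statistics are computed per trial, per muscle, per band.  A switch
(``across="frames"``, the default) is the adopted reading; the
alternative across-trial normalization is deliberately not implemented
here because it would pull group-mean patterns toward zero and defeat
averaging.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .segmentation import PHASE_NAMES, PhaseEvents
from .wavelet import IntensityMap

__all__ = [
    "NormalizedPattern",
    "time_normalize",
    "z_normalize",
    "normalize_pattern",
    "average_patterns",
    "export_map",
]

FRAMES_PER_PHASE = 100


@dataclass
class NormalizedPattern:
    """Per-muscle z-normalized wavelet pattern, 14 bands x 300 frames."""

    muscle: str
    values: np.ndarray
    band_freqs: np.ndarray
    subject_id: str = ""
    group: str = ""
    limb: str = ""
    trial_index: int = 0
    frames_per_phase: int = FRAMES_PER_PHASE

    @property
    def phase_boundaries(self) -> tuple[int, ...]:
        f = self.frames_per_phase
        return (0, f, 2 * f, 3 * f)

    def phase_columns(self, phase_scope: str) -> slice:
        """Frame slice selecting all phases or one named phase."""
        if phase_scope == "all":
            return slice(0, 3 * self.frames_per_phase)
        if phase_scope not in PHASE_NAMES:
            raise ConfigurationError(f"unknown phase scope {phase_scope!r}")
        i = PHASE_NAMES.index(phase_scope)
        return slice(i * self.frames_per_phase, (i + 1) * self.frames_per_phase)


def time_normalize(
    imap: IntensityMap, events: PhaseEvents, frames_per_phase: int = FRAMES_PER_PHASE
) -> np.ndarray:
    """Warp each hop phase to ``frames_per_phase`` frames; concatenate.

    Per phase, the band values are linearly interpolated at
    ``frames_per_phase`` positions evenly spaced over the phase's sample
    range, endpoints inclusive, so constants and linear ramps survive
    exactly and a phase of exactly ``frames_per_phase`` samples is
    reproduced at matching positions.
    """
    values = imap.values
    n_bands, n_samples = values.shape
    if events.t3 >= n_samples:
        raise ConfigurationError("events extend beyond the intensity map")
    out = np.empty((n_bands, 3 * frames_per_phase), dtype=float)
    for i, phase in enumerate(PHASE_NAMES):
        sl = events.phase_slice(phase)
        length = sl.stop - sl.start
        if length < 2:
            raise ConfigurationError(f"degenerate phase {phase!r} of {length} sample(s)")
        grid = sl.start + (length - 1) * np.linspace(0.0, 1.0, frames_per_phase)
        cols = slice(i * frames_per_phase, (i + 1) * frames_per_phase)
        sample_idx = np.arange(n_samples)
        for b in range(n_bands):
            out[b, cols] = np.interp(grid, sample_idx, values[b])
    return out


def z_normalize(matrix: np.ndarray) -> np.ndarray:
    """Per-band z-score over frames: mean 0 and SD 1 per row.

    A zero-variance band cannot be scaled; it is set to all zeros and a
    warning is emitted rather than silently propagating NaNs.
    """
    m = np.asarray(matrix, dtype=float)
    mean = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True)
    # relative floor: an SD at rounding-noise level is no variance at all
    floor = 1e-12 * np.maximum(np.abs(mean), 1.0)
    flat = (sd <= floor).ravel()
    if flat.any():
        warnings.warn(
            f"zero-variance band(s) {np.flatnonzero(flat).tolist()} set to zeros",
            RuntimeWarning,
            stacklevel=2,
        )
    safe_sd = np.where(flat[:, None], 1.0, sd)
    out = (m - mean) / safe_sd
    out[flat, :] = 0.0
    return out


def normalize_pattern(
    imap: IntensityMap,
    events: PhaseEvents,
    frames_per_phase: int = FRAMES_PER_PHASE,
    subject_id: str = "",
    group: str = "",
    limb: str = "",
    trial_index: int = 0,
) -> NormalizedPattern:
    """Time-warp then z-normalize one intensity map (warp-first order)."""
    warped = time_normalize(imap, events, frames_per_phase)
    return NormalizedPattern(
        muscle=imap.muscle,
        values=z_normalize(warped),
        band_freqs=np.asarray(imap.band_freqs, dtype=float),
        subject_id=subject_id,
        group=group,
        limb=limb,
        trial_index=trial_index,
        frames_per_phase=frames_per_phase,
    )


def average_patterns(patterns, by=("group", "limb", "muscle")):
    """Frame- and band-wise mean pattern within each grouping key.

    Returns a dict mapping the key tuple to ``(mean_values, count)``.
    """
    patterns = list(patterns)
    if not patterns:
        raise ConfigurationError("cannot average an empty pattern collection")
    shape = patterns[0].values.shape
    groups: dict[tuple, list[np.ndarray]] = {}
    for p in patterns:
        if p.values.shape != shape:
            raise ConfigurationError("patterns must share one shape to be averaged")
        key = tuple(getattr(p, k) for k in by)
        groups.setdefault(key, []).append(p.values)
    return {k: (np.mean(v, axis=0), len(v)) for k, v in groups.items()}


def export_map(pattern: NormalizedPattern, path: str | Path) -> list[Path]:
    """Write a pattern's numeric map, a [0,1]-rescaled display copy, and metadata.

    The rescale is min-max over the whole map and exists only for
    display; an all-constant map rescales to all zeros by convention.
    Returns the three paths written.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [f"frame_{i}" for i in range(pattern.values.shape[1])]
    idx = [f"{f:.2f}Hz" for f in pattern.band_freqs]
    raw = pd.DataFrame(pattern.values, index=idx, columns=cols)
    raw.to_csv(path)
    lo, hi = pattern.values.min(), pattern.values.max()
    scaled_vals = np.zeros_like(pattern.values) if hi == lo else (pattern.values - lo) / (hi - lo)
    scaled_path = path.with_name(path.stem + "_scaled" + path.suffix)
    pd.DataFrame(scaled_vals, index=idx, columns=cols).to_csv(scaled_path)
    meta_path = path.with_suffix(".meta.json")
    meta_path.write_text(
        json.dumps(
            {
                "muscle": pattern.muscle,
                "subject_id": pattern.subject_id,
                "group": pattern.group,
                "limb": pattern.limb,
                "trial_index": pattern.trial_index,
                "phase_boundaries": list(pattern.phase_boundaries),
                "normalization_order": "time-warp then z-score",
            },
            indent=1,
        )
    )
    return [path, scaled_path, meta_path]


def read_map(path: str | Path) -> np.ndarray:
    """Read back a map written by :func:`export_map` (values only)."""
    return pd.read_csv(Path(path), index_col=0).to_numpy(dtype=float)
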