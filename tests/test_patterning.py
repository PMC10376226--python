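import numpy as np
import pytest

import hopwave as hw
from hopwave.errors import ConfigurationError
from hopwave.patterning import (
    average_patterns,
    export_map,
    normalize_pattern,
    read_map,
    time_normalize,
    z_normalize,
)
from hopwave.segmentation import PhaseEvents
from hopwave.wavelet import IntensityMap


def make_map(values, fs=3000.0):
    values = np.atleast_2d(values)
    return IntensityMap(
        muscle="VM", values=values, band_freqs=np.arange(values.shape[0]) + 1.0, fs=fs
    )


class TestTimeNormalize:
    events = PhaseEvents(0, 150, 400, 520)

    def test_constant_band_stays_constant(self):
        m = make_map(np.full((3, 600), 7.0))
        out = time_normalize(m, self.events)
        assert out.shape == (3, 300)
        assert np.allclose(out, 7.0)

    def test_linear_ramp_endpoints_preserved(self):
        m = make_map(np.arange(600.0))
        out = time_normalize(m, self.events)
        # take-off spans samples 0..149: endpoints preserved, still linear
        take_off = out[0, :100]
        assert take_off[0] == pytest.approx(0.0)
        assert take_off[-1] == pytest.approx(149.0)
        assert np.allclose(np.diff(take_off), np.diff(take_off)[0])

    def test_identity_on_hundred_sample_phase(self):
        ev = PhaseEvents(0, 100, 200, 299)
        m = make_map(np.arange(400.0))
        out = time_normalize(m, ev)
        assert np.allclose(out[0, :100], np.arange(100.0))

    def test_degenerate_phase_rejected(self):
        ev = PhaseEvents(0, 1, 400, 520)
        with pytest.raises(ConfigurationError):
            time_normalize(make_map(np.ones(600)), ev)


class TestZNormalize:
    def test_mean_zero_sd_one(self):
        out = z_normalize(np.arange(300.0)[None, :])
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std() == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self, rng):
        x = rng.standard_normal((14, 300))
        assert np.allclose(z_normalize(x), z_normalize(10.0 * x), atol=1e-10)

    def test_constant_band_zeroed_with_warning(self):
        x = np.vstack([np.full(300, 3.0), np.arange(300.0)])
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            out = z_normalize(x)
        assert np.all(out[0] == 0.0)
        assert out[1].std() == pytest.approx(1.0)


class TestGainInvariance:
    def test_pipeline_invariant_to_emg_gain(self, bank, clean_trial):
        # intensity -> warp -> z-score removes any overall amplitude factor
        trial, truth = clean_trial
        ev = PhaseEvents(truth.t0, truth.t1, truth.t2, truth.t3)
        x = trial.emg["RF"].to_numpy()
        p1 = normalize_pattern(hw.intensity(x, bank, trial.fs_emg, "RF"), ev)
        p2 = normalize_pattern(hw.intensity(10.0 * x, bank, trial.fs_emg, "RF"), ev)
        assert p1.values.shape == (14, 300)
        assert np.allclose(p1.values, p2.values, atol=1e-6)


class TestAveragePatterns:
    def _pattern(self, values, **labels):
        return hw.NormalizedPattern(
            muscle=labels.pop("muscle", "VM"),
            values=values,
            band_freqs=np.arange(values.shape[0]) + 1.0,
            **labels,
        )

    def test_identical_patterns_average_to_themselves(self, rng):
        v = rng.standard_normal((14, 300))
        pats = [self._pattern(v.copy(), group="ACLR", limb="index") for _ in range(3)]
        out = average_patterns(pats)
        (key, (mean, count)), = out.items()
        assert count == 3
        assert np.allclose(mean, v)

    def test_opposite_patterns_cancel(self, rng):
        v = rng.standard_normal((14, 300))
        pats = [
            self._pattern(v, group="ACLR", limb="index"),
            self._pattern(-v, group="ACLR", limb="index"),
        ]
        (mean, count), = average_patterns(pats).values()
        assert np.allclose(mean, 0.0)

    def test_grouping_keys_respected(self, rng):
        pats = [
            self._pattern(rng.standard_normal((2, 6)), group=g, limb="index")
            for g in ("ACLR", "Control")
        ]
        out = average_patterns(pats, by=("group",))
        assert set(out) == {("ACLR",), ("Control",)}

    def test_empty_collection_rejected(self):
        with pytest.raises(ConfigurationError):
            average_patterns([])


class TestExportMap:
    def test_round_trip_and_scaled_copy(self, tmp_path, rng):
        v = rng.standard_normal((14, 300))
        p = hw.NormalizedPattern(muscle="ST", values=v, band_freqs=np.linspace(7, 624, 14))
        raw_path, scaled_path, meta_path = export_map(p, tmp_path / "st.csv")
        assert np.allclose(read_map(raw_path), v, atol=1e-12)
        scaled = read_map(scaled_path)
        assert scaled.min() == pytest.approx(0.0) and scaled.max() == pytest.approx(1.0)
        import json

        meta = json.loads(meta_path.read_text())
        assert meta["phase_boundaries"] == [0, 100, 200, 300]

    def test_constant_pattern_scales_to_zeros(self, tmp_path):
        p = hw.NormalizedPattern(
            muscle="ST", values=np.full((14, 300), 2.0), band_freqs=np.linspace(7, 624, 14)
        )
        _, scaled_path, _ = export_map(p, tmp_path / "c.csv")
        assert np.all(read_map(scaled_path) == 0.0)
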