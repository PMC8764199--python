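"""Band power, delta/theta ratio, normative z-transform, regions."""

import numpy as np
import pandas as pd
import pytest

from eegmic import (EEGRecording, NormativeReference, band_power,
                    delta_theta_ratio, regional_means, zscore_ratio)
from eegmic.recording import TEN_TWENTY_19
from eegmic.spectral import (DELTA_BAND, NINE_REGIONS, THETA_BAND,
                             reference_from_ratios)


def tone_recording(components, fs=256.0, seconds=60.0, n_channels=2, seed=0):
    """Sum of sinusoids, identical on all channels."""
    rng = np.random.default_rng(seed)
    t = np.arange(int(fs * seconds)) / fs
    wave = sum(amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
               for f, amp in components)
    return EEGRecording(np.tile(wave, (n_channels, 1)), fs)


class TestBandPower:
    def test_single_tone_lands_in_theta(self):
        rec = tone_recording([(6.0, 1.0)])
        theta = band_power(rec, THETA_BAND)
        total = band_power(rec, (1.0, 40.0))
        assert np.all(theta / total >= 0.95)

    def test_white_noise_bandwidth_ratio(self, rng):
        rec = EEGRecording(rng.standard_normal((3, 256 * 300)), 256.0)
        ratio = band_power(rec, DELTA_BAND) / band_power(rec, THETA_BAND)
        assert np.all(np.abs(ratio - 0.75) / 0.75 < 0.10)

    def test_two_to_one_amplitudes_give_ratio_four(self):
        rec = tone_recording([(2.0, 2.0), (6.0, 1.0)])
        ratio = band_power(rec, DELTA_BAND) / band_power(rec, THETA_BAND)
        assert np.all(np.abs(ratio - 4.0) / 4.0 < 0.05)

    def test_partition_sums_to_total(self, rng):
        rec = EEGRecording(rng.standard_normal((2, 256 * 120)), 256.0)
        parts = [(1.0, 4.0), (4.0, 8.0), (8.0, 13.0), (13.0, 30.0),
                 (30.0, 40.0)]
        total = band_power(rec, (1.0, 40.0))
        summed = sum(band_power(rec, b) for b in parts)
        assert np.all(np.abs(summed - total) / total < 0.02)

    def test_too_short_recording_rejected(self):
        rec = EEGRecording(np.random.default_rng(0).standard_normal((2, 100)),
                           256.0)
        with pytest.raises(ValueError):
            band_power(rec, DELTA_BAND)


class TestDeltaThetaRatio:
    def test_equal_tones_give_unity(self):
        rec = tone_recording([(2.0, 1.0), (6.0, 1.0)])
        table = delta_theta_ratio(rec)
        assert np.all(np.abs(table.ratio - 1.0) < 0.05)

    def test_zero_theta_flagged(self):
        rec = tone_recording([(2.0, 1.0)])
        table = delta_theta_ratio(rec)
        # a pure delta tone leaves only leakage in theta; force exact zero
        table.theta_power[:] = 0.0
        rec2 = tone_recording([(2.0, 1.0)])
        import eegmic.spectral as sp
        delta = sp.band_power(rec2, sp.DELTA_BAND)
        tab = sp.BandPowerTable(channels=list(rec2.channel_names),
                                delta_power=delta,
                                theta_power=np.zeros_like(delta),
                                ratio=np.full_like(delta, np.nan),
                                flagged_channels=list(rec2.channel_names))
        assert np.isnan(tab.ratio).all()
        assert tab.flagged_channels == list(rec2.channel_names)


class TestZScore:
    def make_ref(self, channels, mean=0.0, sd=0.5):
        return NormativeReference(pd.DataFrame({
            "channel": channels,
            "mean_log_ratio": mean,
            "sd_log_ratio": sd,
        }))

    def test_ratio_at_reference_mean_gives_zero(self):
        rec = tone_recording([(2.0, 1.0), (6.0, 1.0)], seconds=30.0)
        table = delta_theta_ratio(rec)
        ref = self.make_ref(table.channels,
                            mean=np.log(table.ratio), sd=0.5)
        out = zscore_ratio(table, ref)
        assert np.allclose(out.z_ratio, 0.0, atol=1e-12)

    def test_extreme_excursions_clip_to_three(self):
        rec = tone_recording([(2.0, 1.0), (6.0, 1.0)], seconds=30.0)
        table = delta_theta_ratio(rec)
        ref = self.make_ref(table.channels,
                            mean=np.log(table.ratio) - 10 * 0.5, sd=0.5)
        out = zscore_ratio(table, ref)
        assert np.allclose(out.z_ratio, 3.0)
        ref_lo = self.make_ref(table.channels,
                               mean=np.log(table.ratio) + 10 * 0.5, sd=0.5)
        out = zscore_ratio(delta_theta_ratio(rec), ref_lo)
        assert np.allclose(out.z_ratio, -3.0)

    def test_z_monotone_in_ratio_until_clip(self):
        channels = ["c1"]
        ref = self.make_ref(channels, mean=0.0, sd=1.0)
        ratios = np.exp(np.linspace(-2.5, 2.5, 11))
        zs = []
        for r in ratios:
            import eegmic.spectral as sp
            tab = sp.BandPowerTable(channels=channels,
                                    delta_power=np.array([r]),
                                    theta_power=np.array([1.0]),
                                    ratio=np.array([r]))
            zs.append(zscore_ratio(tab, ref).z_ratio[0])
        assert np.all(np.diff(zs) > 0)

    def test_missing_channel_rejected(self):
        ref = self.make_ref(["Fp1"])
        with pytest.raises(ValueError):
            ref.lookup(["Fp1", "Oz"])

    def test_same_law_z_is_roughly_standard_normal(self, rng):
        # reference built from 200 subjects of one log-normal law; new
        # subjects from the same law must give z ~ N(0, 1) truncated at 3
        channels = TEN_TWENTY_19
        ref_ratios = np.exp(rng.normal(0.2, 0.4, size=(200, 19)))
        ref = reference_from_ratios(channels, ref_ratios)
        test_ratios = np.exp(rng.normal(0.2, 0.4, size=(500, 19)))
        z = (np.log(test_ratios) - ref.table["mean_log_ratio"].to_numpy()) \
            / ref.table["sd_log_ratio"].to_numpy()
        z = np.clip(z, -3, 3)
        assert abs(z.mean()) < 0.05
        assert abs(z.std() - 1.0) < 0.05


class TestRegions:
    def test_constant_channels_give_constant_regions(self):
        values = {ch: 2.5 for ch in TEN_TWENTY_19}
        out = regional_means(values)
        assert np.allclose(out.to_numpy(), 2.5)
        assert set(out.index) == set(NINE_REGIONS)

    def test_left_frontal_arithmetic(self):
        values = {ch: 0.0 for ch in TEN_TWENTY_19}
        values.update({"Fp1": 1.0, "F3": 2.0, "F7": 3.0})
        out = regional_means(values)
        assert out["left_frontal"] == pytest.approx(2.0)

    def test_frontal_is_mean_of_electrodes_not_subregions(self):
        values = {ch: 0.0 for ch in TEN_TWENTY_19}
        values.update({"Fp1": 1.0, "F3": 1.0, "F7": 1.0, "Fz": 8.0})
        out = regional_means(values)
        # 7-electrode mean: (1+1+1+8+0+0+0)/7
        assert out["frontal"] == pytest.approx(11.0 / 7.0)
        sub_mean = (out["left_frontal"] + out["right_frontal"]) / 2
        assert out["frontal"] != pytest.approx(sub_mean)

    def test_invariant_to_channel_ordering(self, rng):
        vals = pd.Series(rng.standard_normal(19), index=TEN_TWENTY_19)
        shuffled = vals.sample(frac=1.0, random_state=3)
        assert np.allclose(regional_means(vals).to_numpy(),
                           regional_means(shuffled).to_numpy())

    def test_missing_electrode_rejected(self):
        with pytest.raises(ValueError):
            regional_means({"Fp1": 1.0})
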