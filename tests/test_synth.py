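import json

import numpy as np
import pytest

from aslt.constants import R_GAS
from aslt.datamodel import PeriodLabel
from aslt.errors import ConfigError
from aslt.io import read_etongue_table, read_quality_table, read_spectra
from aslt.kinetics import fit_zero_order
from aslt.synth import (
    SimulationConfig,
    gen_etongue_study,
    gen_full_bundle,
    gen_nir_study,
    gen_quality_study,
)
from aslt.taste import run_fda


class TestConfig:
    def test_duration_must_divide_by_interval(self):
        with pytest.raises(ConfigError):
            SimulationConfig(durations_d=(100.0,), sampling_intervals_d=(7.0,),
                             temperatures_K=(318.15,))

    def test_negative_noise_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(noise_rel=-0.1)

    def test_default_design_matches_study_layout(self):
        cfg = SimulationConfig()
        assert len(cfg.sampling_days(298.15)) == 7
        assert len(cfg.sampling_days(308.15)) == 12
        assert len(cfg.sampling_days(318.15)) == 13


class TestQualityStudy:
    def test_zero_noise_means_follow_kinetic_law(self):
        cfg = SimulationConfig(noise_rel=0.0, seed=2)
        for s in gen_quality_study(cfg):
            params = next(
                p for p in cfg.indices
                if (p.index_name, p.component) == (s.index_name, s.component)
            )
            k = params.A_classic * np.exp(-params.Ea / (R_GAS * s.temperature_K))
            f = fit_zero_order(s)
            assert abs(f.k_hat) == pytest.approx(k, rel=1e-8)
            assert f.A0_hat == pytest.approx(params.A0, rel=1e-8)
            assert f.R2 == pytest.approx(1.0)

    def test_sensory_series_truncated_at_scale_floor(self):
        cfg = SimulationConfig(noise_rel=0.0)
        sens45 = next(
            s for s in gen_quality_study(cfg)
            if s.index_name == "sensory_score" and s.temperature_K == 318.15
        )
        assert sens45.values.min() > 1.0
        assert len(sens45) < 13  # shorter than the full 45 °C grid

    def test_seed_determinism(self):
        a = gen_quality_study(SimulationConfig(seed=5))
        b = gen_quality_study(SimulationConfig(seed=5))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.replicate_values, y.replicate_values)

    def test_different_seeds_differ(self):
        a = gen_quality_study(SimulationConfig(seed=5))
        b = gen_quality_study(SimulationConfig(seed=6))
        assert not np.allclose(a[0].replicate_values, b[0].replicate_values)


class TestETongueStudy:
    def test_sample_count_matches_study(self):
        profiles, labels = gen_etongue_study(SimulationConfig())
        assert len(profiles) == 75  # 13·3 at 45 °C + 12·3 at 35 °C
        assert len(labels) == 75

    def test_sourness_rises_umami_falls_across_periods(self):
        cfg = SimulationConfig()
        assert cfg.etongue_means["sourness"][0] == 14.79
        profiles, labels = gen_etongue_study(cfg)
        sour = {p: [] for p in PeriodLabel}
        umami = {p: [] for p in PeriodLabel}
        for prof, lab in zip(profiles, labels):
            sour[lab].append(prof.attributes["sourness"])
            umami[lab].append(prof.attributes["umami"])
        sour_means = [np.mean(sour[p]) for p in PeriodLabel]
        umami_means = [np.mean(umami[p]) for p in PeriodLabel]
        assert sour_means[0] < sour_means[1] < sour_means[2]
        assert sour_means[2] >= 17.0
        assert umami_means[0] > umami_means[1] > umami_means[2]

    def test_tight_clusters_classified_perfectly(self):
        cfg = SimulationConfig(
            etongue_sds={k: 0.01 for k in SimulationConfig().etongue_sds}
        )
        profiles, labels = gen_etongue_study(cfg)
        res = run_fda(profiles[:39], labels[:39], seed=0)
        assert res.calibration_accuracy_pct == 100.0
        assert res.prediction_accuracy_pct == 100.0

    def test_seed_determinism(self):
        p1, _ = gen_etongue_study(SimulationConfig(seed=8))
        p2, _ = gen_etongue_study(SimulationConfig(seed=8))
        assert p1[0].attributes == p2[0].attributes


class TestNIRStudy:
    def test_amplitude_tracks_storage_day_without_noise(self):
        spectra = gen_nir_study(SimulationConfig(seed=3, nir_noise_rel=0.0))
        wl = spectra[0].wavelengths_nm
        i1450 = int(np.argmin(np.abs(wl - 1450.0)))
        amps = [s.absorbances[i1450] for s in spectra]
        days = [s.storage_day for s in spectra]
        assert np.corrcoef(amps, days)[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_noisy_amplitude_correlates_with_total_acid(self):
        spectra = gen_nir_study(SimulationConfig(seed=3))
        wl = spectra[0].wavelengths_nm
        i1450 = int(np.argmin(np.abs(wl - 1450.0)))
        amps = [s.absorbances[i1450] for s in spectra]
        acid = [s.total_acid for s in spectra]
        assert np.corrcoef(amps, acid)[0, 1] >= 0.9

    def test_generated_peaks_near_configured_centers(self):
        from aslt.ann import find_peaks

        for s in gen_nir_study(SimulationConfig(seed=9))[:5]:
            peaks = find_peaks(s, min_prominence=0.1)
            for center in (960.0, 1150.0, 1450.0):
                assert np.min(np.abs(peaks - center)) <= 10.0


class TestFullBundle:
    def test_bundle_round_trips_through_io(self, tmp_path):
        cfg = SimulationConfig(seed=4, nir_samples=12)
        paths = gen_full_bundle(cfg, tmp_path / "study")
        series = read_quality_table(paths["quality"])
        assert len(series) == 18
        gen = gen_quality_study(cfg)
        by_key = {s.key: s for s in gen}
        for s in series:
            np.testing.assert_allclose(s.values, by_key[s.key].values, rtol=1e-12)
        profiles = read_etongue_table(paths["etongue"])
        assert len(profiles) == 75
        spectra = read_spectra(paths["spectra_manifest"])
        assert len(spectra) == 12
        truth = json.loads((tmp_path / "study" / "truth.json").read_text())
        sens = next(i for i in truth["indices"] if i["index"] == "sensory_score")
        assert sens["A_classic"] == 3.412e10
        assert sens["Ea"] == 70070.0

    def test_two_seeds_same_schema_different_values(self, tmp_path):
        p1 = gen_full_bundle(SimulationConfig(seed=1, nir_samples=10), tmp_path / "a")
        p2 = gen_full_bundle(SimulationConfig(seed=2, nir_samples=10), tmp_path / "b")
        s1 = read_quality_table(p1["quality"])
        s2 = read_quality_table(p2["quality"])
        assert [s.key for s in s1] == [s.key for s in s2]
        assert not np.allclose(s1[0].values, s2[0].values)
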