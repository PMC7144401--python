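"""Synthetic cohort generator: trajectories, signals, questionnaires."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import signal as sps
from scipy import stats as sct

from somnostat import (
    SimulationConfig,
    Stage,
    TransitionModel,
    mean_vigilance_value,
    simulate_cohort,
    simulate_vigilance_trajectory,
    synthesize_recording,
)
from somnostat.simulate import (
    TRAIT_LOADING,
    ConfigurationError,
    NoiseScales,
    _simulate_paths,
)
from tests.conftest import constant_sequence

FS = 200


def band_power(x, fs, lo, hi):
    freqs, psd = sps.periodogram(x, fs=fs)
    return psd[(freqs >= lo) & (freqs < hi)].sum() * (freqs[1] - freqs[0])


class TestTransitionModel:
    def test_rows_sum_to_one(self):
        model = TransitionModel()
        for drift in (-1.5, 0.0, 2.0):
            mat = model.matrix(drift)
            assert np.allclose(mat.sum(axis=1), 1.0, atol=1e-12)

    def test_invalid_rows_rejected(self):
        with pytest.raises(ConfigurationError):
            TransitionModel(initial=(0.5,) * 7)
        with pytest.raises(ConfigurationError):
            TransitionModel(p_down=(0.6, 0.6, 0.6, 0.6, 0.6, 0.6, 0.5))

    def test_absorbing_state_gives_constant_trajectory(self):
        model = TransitionModel(
            initial=(0, 1, 0, 0, 0, 0, 0),
            p_down=(0.0,) * 7,
            p_up=(0.0,) * 7,
        )
        config = SimulationConfig(transition_model=model, duration=300)
        seq = simulate_vigilance_trajectory(config, trait=1.0, seed=9)
        assert all(s is Stage.A1 for s in seq.labels)


class TestTrajectories:
    def test_deterministic_given_seed(self):
        config = SimulationConfig(duration=300)
        a = simulate_vigilance_trajectory(config, trait=0.3, seed=21)
        b = simulate_vigilance_trajectory(config, trait=0.3, seed=21)
        assert np.array_equal(a.codes, b.codes)

    def test_zero_coupling_seeds_share_marginal_distribution(self):
        # at coupling 0 the trajectory law is trait-free: two independent
        # replicate batches must agree on the marginal stage distribution
        config = SimulationConfig(coupling=0.0, duration=300)
        model = config.transition_model
        counts = []
        for seed in (100, 200):
            rng = np.random.default_rng(seed)
            codes = _simulate_paths(rng, model, np.zeros(200), config.duration)
            counts.append(
                np.array([(codes == k).mean() for k in range(7)])
            )
        diff = counts[0] - counts[1]
        # binomial-style standard error per stage over 200 replicates
        p_bar = (counts[0] + counts[1]) / 2
        se = np.sqrt(2 * p_bar * (1 - p_bar) / (200 * config.duration / 10))
        assert np.all(np.abs(diff) <= np.maximum(3 * se, 0.02))

    def test_higher_trait_lowers_mean_vigilance(self):
        config = SimulationConfig(duration=300)
        model = config.transition_model
        rng = np.random.default_rng(5)
        sleepy = _simulate_paths(
            rng, model, np.full(100, config.coupling * 2.0), 300
        )
        rng = np.random.default_rng(6)
        alert = _simulate_paths(
            rng, model, np.full(100, config.coupling * -2.0), 300
        )
        assert (7 - sleepy.mean()) < (7 - alert.mean())

    def test_too_short_duration_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_vigilance_trajectory(
                SimulationConfig(duration=30), trait=0.0, seed=0
            )


class TestRecordingSynthesis:
    def test_a1_has_occipital_alpha_dominance_every_second(self, montage):
        config = SimulationConfig()
        rec = synthesize_recording(constant_sequence(Stage.A1, 60), config, seed=2)
        occ = [i for i, ch in enumerate(montage) if montage[ch] == "occipital"]
        fro = [i for i, ch in enumerate(montage) if montage[ch] == "frontal"]
        for sec in range(60):
            seg = rec.data[:, sec * FS : (sec + 1) * FS]
            occ_alpha = np.mean([band_power(seg[i], FS, 8, 12) for i in occ])
            fro_alpha = np.mean([band_power(seg[i], FS, 8, 12) for i in fro])
            assert occ_alpha > fro_alpha

    def test_b23_doubles_slow_power_relative_to_wake(self):
        config = SimulationConfig()
        drowsy = synthesize_recording(constant_sequence(Stage.B23, 30), config, seed=3)
        wake = synthesize_recording(constant_sequence(Stage.STAGE_0, 30), config, seed=3)
        for sec in range(30):
            slow_d = band_power(drowsy.data[0, sec * FS : (sec + 1) * FS], FS, 1, 8)
            slow_w = band_power(wake.data[0, sec * FS : (sec + 1) * FS], FS, 1, 8)
            assert slow_d >= 2 * slow_w

    def test_c_seconds_carry_a_spindle_band_burst(self):
        config = SimulationConfig()
        rec = synthesize_recording(constant_sequence(Stage.C, 30), config, seed=4)
        wake = synthesize_recording(constant_sequence(Stage.STAGE_0, 30), config, seed=4)
        for sec in range(30):
            burst = band_power(rec.data[0, sec * FS : (sec + 1) * FS], FS, 11, 16)
            base = band_power(wake.data[0, sec * FS : (sec + 1) * FS], FS, 11, 16)
            assert burst > 5 * base

    def test_deterministic_given_seed(self):
        config = SimulationConfig()
        seq = constant_sequence(Stage.A2, 10)
        a = synthesize_recording(seq, config, seed=8)
        b = synthesize_recording(seq, config, seed=8)
        assert np.array_equal(a.data, b.data)


class TestCohort:
    def test_default_group_sizes_yield_193_subjects(self):
        config = SimulationConfig(duration=60)
        cohort, truth = simulate_cohort(config)
        assert len(cohort) == 193
        assert len(truth.sequences) == 193
        counts = {g: truth.groups.count(g) for g in set(truth.groups)}
        assert counts == {"HC": 66, "OB": 68, "DEP": 16, "OBDEP": 43}

    def test_empty_cohort(self):
        config = SimulationConfig(
            group_sizes={"HC": 0, "OB": 0, "DEP": 0, "OBDEP": 0}
        )
        cohort, truth = simulate_cohort(config)
        assert len(cohort) == 0 and truth.traits.size == 0

    def test_reproducible_bitwise(self, small_config):
        a, truth_a = simulate_cohort(small_config)
        b, truth_b = simulate_cohort(small_config)
        assert a.to_frame().equals(b.to_frame())
        assert all(
            np.array_equal(x.codes, y.codes)
            for x, y in zip(truth_a.sequences, truth_b.sequences)
        )
        # per-subject recordings are reproducible from the stored seed
        sa = a.subjects[0]
        rec1 = synthesize_recording(truth_a.sequences[0], small_config, sa.recording_seed)
        rec2 = synthesize_recording(truth_b.sequences[0], small_config, sa.recording_seed)
        assert np.array_equal(rec1.data, rec2.data)

    def test_group_labels_recomputable_from_bmi_and_bdi(self, small_config):
        cohort, truth = simulate_cohort(small_config)
        for subject, g in zip(cohort.subjects, truth.groups):
            assert subject.group == g

    def test_trait_kss_correlation_matches_copula_target(self):
        # Pearson correlation of trait and the KSS latent is the loading
        # (0.8); the Gaussian-copula Spearman equivalent is
        # (6/pi) asin(rho/2); discretization to the 1-10 scale shrinks it
        # slightly, so the recovered value must sit within +-0.1
        config = SimulationConfig(
            group_sizes={"HC": 200, "OB": 200, "DEP": 0, "OBDEP": 0},
            duration=60,
            coupling=0.8,
            group_effects={"HC": 0.0, "OB": 0.0},
            seed=13,
        )
        cohort, truth = simulate_cohort(config)
        kss = cohort.to_frame()["kss_pre"].to_numpy()
        target = 6 / math.pi * math.asin(TRAIT_LOADING / 2)
        rho = sct.spearmanr(truth.traits, kss).statistic
        assert rho == pytest.approx(target, abs=0.1)

    def test_depressed_groups_report_more_presleepiness(self):
        # median ordering DEP, OBDEP >= HC, OB on KSS/SSS pre; per-cohort
        # medians of a 1-10 ordinal at n=15 are +-1 noisy, so the ordering
        # is checked on the medians averaged over 50 replicate cohorts
        medians = []
        for seed in range(50):
            config = SimulationConfig(
                group_sizes={"HC": 15, "OB": 15, "DEP": 15, "OBDEP": 15},
                duration=60,
                seed=seed,
            )
            df = simulate_cohort(config)[0].to_frame()
            medians.append(df.groupby("group")[["kss_pre", "sss_pre"]].median())
        mean_med = sum(medians) / len(medians)
        for col in ("kss_pre", "sss_pre"):
            assert mean_med.loc[["DEP", "OBDEP"], col].min() >= mean_med.loc[
                ["HC", "OB"], col
            ].max()

    def test_asleep_distribution_spans_levels(self, small_config):
        df = simulate_cohort(small_config)[0].to_frame()
        assert set(df["asleep"]) <= {1, 2, 3, 4}
        assert df["asleep"].nunique() >= 3
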