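import numpy as np
import pandas as pd
import pytest

from segrel.annotation_io import read_annotations_csv, read_timing_csv
from segrel.deviations import compute_deviations, reference_medians
from segrel.heuristics import peaks_to_word_count
from segrel.mixture_reliability import MixtureSpec, PsoConfig, pso_fit, weighted_sigma_summary
from segrel.synthetic_data import (
    GeneratorConfig,
    generate_study,
    omission_positions,
    write_study,
)


def _uniform_error_config(spec, **kwargs):
    models = {(m, r): spec
              for m in ("ponss", "baseline")
              for r in ("fast", "medium", "slow")}
    return GeneratorConfig(error_models=models, **kwargs)


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        config = GeneratorConfig(n_speakers=2, trials_per_speaker=6, seed=42)
        a = generate_study(config)
        b = generate_study(config)
        for key in a:
            pd.testing.assert_frame_equal(a[key], b[key])

    def test_different_seed_differs(self):
        a = generate_study(GeneratorConfig(n_speakers=2, trials_per_speaker=6, seed=1))
        b = generate_study(GeneratorConfig(n_speakers=2, trials_per_speaker=6, seed=2))
        assert not a["annotations"]["time_ms"].equals(b["annotations"]["time_ms"])


class TestGeneratedDataValidity:
    def test_round_trips_through_io_validation(self, small_study, tmp_path):
        write_study(small_study, tmp_path)
        ann = read_annotations_csv(tmp_path / "annotations.csv")
        timing = read_timing_csv(tmp_path / "timing.csv")
        assert len(ann) == len(small_study["annotations"])
        assert len(timing) == len(small_study["timing_events"])

    def test_offsets_after_onsets(self, small_study):
        wide = small_study["annotations"].pivot_table(
            index=["token_id", "annotator_id", "modality"],
            columns="boundary", values="time_ms", aggfunc="first",
        )
        assert (wide["offset"] > wide["onset"]).all()

    def test_textgrid_export_parses_back(self, small_study, tmp_path):
        write_study(small_study, tmp_path, textgrids=True)
        from segrel.annotation_io import read_textgrid

        grids = sorted((tmp_path / "textgrids").glob("*.TextGrid"))
        assert grids
        doc = read_textgrid(grids[0])
        assert doc.tiers[0].name == "words"
        assert any(iv.text for iv in doc.tiers[0].intervals)


class TestErrorModel:
    def test_single_component_sd_recovered(self):
        """With a pure narrow component (sigma 1.5 ms), the SD of generated
        boundary errors against truth matches to within 3%."""
        spec = MixtureSpec(sigma=(1.5, 1.5, 2.5), theta=(1.0, 0.0, 0.0))
        config = _uniform_error_config(spec, n_speakers=4, trials_per_speaker=12,
                                       quantization_prob=0.0, seed=7)
        study = generate_study(config)
        merged = study["annotations"].merge(study["true_boundaries"], on="token_id")
        err = np.where(merged["boundary"] == "onset",
                       merged["time_ms"] - merged["onset_ms"],
                       merged["time_ms"] - merged["offset_ms"])
        assert len(err) > 5_000
        assert np.std(err) == pytest.approx(1.5, rel=0.03)

    def test_quantization_creates_20ms_side_peaks(self):
        spec = MixtureSpec(sigma=(1.0, 4.0, 15.0), theta=(0.3, 0.5, 0.2))
        def side_peak_mass(q):
            config = _uniform_error_config(
                spec, n_speakers=4, trials_per_speaker=12,
                quantization_prob=q, retrim_fraction=1.0, seed=3)
            study = generate_study(config)
            ann = study["annotations"]
            pon = ann[ann["modality"] == "ponss"].merge(
                study["true_boundaries"], on="token_id")
            err = np.where(pon["boundary"] == "onset",
                           pon["time_ms"] - pon["onset_ms"],
                           pon["time_ms"] - pon["offset_ms"])
            at_peak = np.mean(np.abs(np.abs(err) - 20.0) < 0.5)
            nearby = np.mean((np.abs(np.abs(err) - 16.0) < 0.5))
            return at_peak, nearby

        peak_q, nearby_q = side_peak_mass(0.3)
        peak_0, _ = side_peak_mass(0.0)
        assert peak_q > 3 * max(peak_0, 1e-6)  # clear local modes at +-20 ms
        assert peak_q > 2 * nearby_q           # modes are local, not a broad bump


class TestOmissionModel:
    def test_all_zero_probabilities_produce_everything(self):
        config = GeneratorConfig(omission_probs=(0,) * 8)
        rng = np.random.default_rng(0)
        assert omission_positions(config, rng) == set(range(1, 9))

    def test_certain_omission_of_final_position(self):
        config = GeneratorConfig(omission_probs=(0,) * 7 + (1,))
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert 8 not in omission_positions(config, rng)

    def test_empirical_rates_monotone_with_position(self):
        config = GeneratorConfig()
        rng = np.random.default_rng(123)
        n = 10_000
        omitted = np.zeros(8)
        for _ in range(n):
            produced = omission_positions(config, rng)
            for pos in range(1, 9):
                if pos not in produced:
                    omitted[pos - 1] += 1
        rates = omitted / n
        assert np.all(np.diff(rates) >= -0.02)
        np.testing.assert_allclose(rates, config.omission_probs, atol=0.02)


class TestPipelineClosure:
    def test_generate_deviate_fit_recovers_weighted_sigma(self):
        """End-to-end: generator -> median references -> mixture fit recovers
        the generating weighted sigma within 20% (median over seeds)."""
        spec = MixtureSpec(sigma=(1.2, 4.0, 15.0), theta=(0.55, 0.35, 0.10))
        target = weighted_sigma_summary(spec)
        errs = []
        for seed in range(5):
            config = _uniform_error_config(
                spec, n_speakers=3, trials_per_speaker=9,
                quantization_prob=0.0, seed=100 + seed)
            study = generate_study(config)
            ann = study["annotations"]
            dev = compute_deviations(ann, reference_medians(ann))
            fit = pso_fit(dev["deviation_ms"].to_numpy(),
                          PsoConfig(n_particles=20, max_iter=300, seed=seed))
            ws = weighted_sigma_summary(fit)
            errs.append(abs(ws - target) / target)
        assert np.median(errs) < 0.20


class TestTimingAndPeaks:
    def test_noiseless_peak_counts_track_produced_words(self):
        config = GeneratorConfig(n_speakers=2, trials_per_speaker=6,
                                 peak_miscount_prob=0.0, seed=5)
        study = generate_study(config)
        produced = study["tokens"].groupby("trial_id").size()
        for _, row in study["peak_counts"].iterrows():
            n = int(produced.get(row["trial_id"], 0))
            assert row["n_peaks"] == 2 * n
            assert peaks_to_word_count(row["n_peaks"]) == n

    def test_rejection_rate_near_configured(self, small_study):
        status = small_study["word_status"]
        rate = 1 - status["accepted"].mean()
        assert 0.01 < rate < 0.10  # configured 5%, binomial noise at n ~ 500

    def test_double_triage_fraction(self, small_study):
        timing = small_study["timing_events"]
        triage = timing[timing["task"] == "triage"]
        passes = triage.groupby("unit_id").size()
        frac_double = (passes >= 2).mean()
        assert 0.12 < frac_double < 0.28  # configured 20%

    def test_interaction_durations_match_lognormal_mean(self, small_study):
        config = GeneratorConfig()
        timing = small_study["timing_events"]
        triage = timing[timing["task"] == "triage"]
        durations = triage["t_end_s"] - triage["t_start_s"]
        assert durations.mean() == pytest.approx(
            config.triage_timing.mean_seconds, rel=0.10)

    def test_timing_pool_feeds_efficiency_analysis(self, small_study):
        from segrel.efficiency_bootstrap import (
            baseline_word_times,
            bootstrap_hours,
            ponss_word_times,
        )

        timing = small_study["timing_events"]
        status = dict(zip(small_study["word_status"]["word_id"],
                          small_study["word_status"]["accepted"]))
        goods = small_study["tokens"].groupby("trial_id").size().to_dict()
        base = baseline_word_times(timing, goods)
        pon = ponss_word_times(timing, status)
        n_good = 100
        d_base = bootstrap_hours(base, n_good, 50, seed=1)
        d_pon = bootstrap_hours(pon, n_good, 50, seed=2)
        # total time conservation for the pipeline modality
        pon_events = timing[timing["task"].isin(["triage", "retrim"])]
        assert pon["total_seconds"].sum() == pytest.approx(
            (pon_events["t_end_s"] - pon_events["t_start_s"]).sum())
        assert d_base.mean > 0 and d_pon.mean > 0


class TestConfigValidation:
    def test_non_monotone_omission_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            GeneratorConfig(omission_probs=(0.5, 0.1) + (0.5,) * 6)

    def test_missing_error_model_rejected(self):
        with pytest.raises(ValueError, match="error model"):
            GeneratorConfig(error_models={})
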