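"""Synthetic trial generator: design, treatment effects, emission, determinism."""

import dataclasses

import numpy as np
import pytest

from pulsechase import conveyor as cv
from pulsechase import enrichment as en
from pulsechase import synthesis as syn

_DAY_POOL = {2, 4, 5, 6, 7, 8, 10, 12, 14, 18, 22, 27, 32, 42}


class TestDefaultDesign:
    def test_structure_and_schedule(self):
        d = syn.default_design(seed=0)
        assert d.n_per_arm == 10
        assert d.label_days == [0, 84]
        assert d.dose_days == [4, 32, 60, 88]
        assert d.dose_days[0] - d.label_days[0] == 4
        assert d.plasma_times_min == [35.0, 185.0, 305.0]

    def test_ten_blood_samples_two_baselines_eight_post(self):
        d = syn.default_design(seed=3)
        for i in range(d.n_per_arm):
            post = [day for ph in (1, 2) for day in d.blood_days[i][ph]]
            assert len(post) == 8
            assert set(post) <= _DAY_POOL
            # plus one pre-label baseline per phase = 10 samples in total
            assert d.baseline_blood_day < 0

    def test_three_paired_sputum_days_per_subject(self):
        d = syn.default_design(seed=3)
        for i in range(d.n_per_arm):
            days = [day for ph in (1, 2) for day in d.sputum_days[i][ph]]
            assert len(days) == 3
            for ph in (1, 2):
                assert set(d.sputum_days[i][ph]) <= set(d.blood_days[i][ph])

    def test_staggering_covers_the_pool(self):
        d = syn.default_design(seed=5)
        sampled = {day for i in range(10) for ph in (1, 2) for day in d.blood_days[i][ph]}
        assert len(sampled) >= 10

    def test_deterministic_in_seed(self):
        assert syn.default_design(seed=9) == syn.default_design(seed=9)
        assert syn.default_design(seed=9) != syn.default_design(seed=10)


class TestEffectiveParams:
    def test_placebo_identity(self):
        base = cv.EOSINOPHIL_DEFAULTS
        sc = syn.TreatmentScenario()
        assert syn.effective_params(base, sc, "placebo", 1, 100.0) == base

    def test_long_term_phase1_limits(self):
        base = cv.EOSINOPHIL_DEFAULTS
        sc = syn.TreatmentScenario()
        eff = syn.effective_params(base, sc, "mepolizumab", 1, 1e9)
        assert eff.production_scale == pytest.approx(0.1)
        assert eff.blood_half_life == pytest.approx(2.5 * 1.8)

    def test_continuity_at_dose_time(self):
        base = cv.EOSINOPHIL_DEFAULTS
        eff = syn.effective_params(base, syn.TreatmentScenario(), "mepolizumab", 1, 0.0)
        assert eff.production_scale == pytest.approx(1.0)

    def test_phase2_multiplier_restores_half_life(self):
        base = cv.EOSINOPHIL_DEFAULTS
        eff = syn.effective_params(base, syn.TreatmentScenario(), "mepolizumab", 2, 50.0)
        assert eff.blood_half_life == pytest.approx(base.blood_half_life)


class TestEmitReadings:
    def test_zero_enrichment_zero_noise_gives_background_ttr(self):
        r = syn.emit_ms_readings(
            0.0, 0.05, en.CorrectionConstants(), 1e5, 0.0, 0,
            sample_id="s", subject_id="P01", study_day=-0.1, phase=1,
            compartment="blood", cell_type="eosinophil",
        )
        assert r.area_m2 / r.area_m0 == pytest.approx(
            syn.NATURAL_BACKGROUND_TTR[en.DNA_CHANNEL]
        )

    def test_negative_enrichment_rejected(self):
        with pytest.raises(ValueError):
            syn.emit_ms_readings(
                -0.01, 0.05, en.CorrectionConstants(), 1e5, 0.0, 0,
                sample_id="s", subject_id="P01", study_day=4, phase=1,
                compartment="blood", cell_type="eosinophil",
            )

    def test_noise_free_inversion(self):
        constants = en.CorrectionConstants()
        p_bar = 0.04
        truth = 0.31
        r = syn.emit_ms_readings(
            truth, p_bar, constants, 2e5, 0.0, 0,
            sample_id="s", subject_id="P01", study_day=7, phase=1,
            compartment="blood", cell_type="eosinophil",
        )
        ttr = en.compute_ttr(r)
        net = ttr - syn.NATURAL_BACKGROUND_TTR[en.DNA_CHANNEL]
        assert en.normalize_enrichment(net, p_bar, constants) == pytest.approx(
            truth, abs=1e-12
        )


class TestGenerateSubject:
    def test_zero_noise_measurements_equal_truth(self, small_noise_free_trial, standards):
        _, table = small_noise_free_trial
        points, errors = en.enrichment_pipeline(table.readings, standards)
        assert errors == []
        merged = points.merge(
            table.truth,
            on=["subject_id", "phase", "study_day", "compartment", "cell_type"],
        )
        np.testing.assert_allclose(
            merged["normalized_enrichment"],
            merged["true_normalized_enrichment"],
            atol=1e-12,
        )

    def test_same_seed_identical_output(self):
        design = syn.default_design(seed=2, n_per_arm=2)
        kw = dict(base_params=None, scenario=syn.TreatmentScenario(), master_seed=4)
        t1 = syn.generate_trial(design, **kw)
        t2 = syn.generate_trial(design, **kw)
        assert t1.readings.equals(t2.readings)
        assert t1.counts.equals(t2.counts)
        assert t1.truth.equals(t2.truth)

    def test_eosinophil_count_collapses_within_two_days_of_dosing(self):
        """Two days after the first dose the treated eosinophil count is, on
        average over many replicates, well below half of baseline."""
        design = syn.default_design(seed=0, n_per_arm=1)
        # force a visit 2 days after the day-4 dose
        design.blood_days[0][1] = [2, 6, 10, 18]
        design.blood_days[0][2] = [2, 6, 10, 18]
        scenario = syn.TreatmentScenario()
        ratios = []
        for seed in range(250):
            profile = syn.SubjectProfile(
                subject_id="M01", arm="mepolizumab", position=0, seed=seed
            )
            sub = syn.generate_subject(
                profile, design, {"eosinophil": cv.EOSINOPHIL_DEFAULTS},
                scenario, cell_types=("eosinophil",), include_sputum=False,
            )
            by_day = {
                (r["phase"], r["study_day"]): r["value"]
                for r in sub["counts"]
                if r["cell_type"] == "eosinophil"
            }
            ratios.append(by_day[(1, 6.0)] / profile.baseline_eos_count)
        assert np.mean(ratios) < 0.5

    def test_basophils_unaffected_by_treatment(self):
        design = syn.default_design(seed=0, n_per_arm=1)
        scenario = dataclasses.replace(
            syn.TreatmentScenario(), count_noise_cv=0.0, ms_area_noise_cv=0.0,
            between_subject_cv=0.0,
        )
        out = {}
        for arm, sid in (("placebo", "P01"), ("mepolizumab", "M01")):
            profile = syn.SubjectProfile(subject_id=sid, arm=arm, position=0, seed=1)
            sub = syn.generate_subject(
                profile, design,
                {"eosinophil": cv.EOSINOPHIL_DEFAULTS, "basophil": cv.BASOPHIL_DEFAULTS},
                scenario,
            )
            out[arm] = sorted(
                (r["phase"], r["study_day"], r["true_normalized_enrichment"])
                for r in sub["truth"]
                if r["cell_type"] == "basophil"
            )
        assert out["placebo"] == out["mepolizumab"]


class TestGenerateTrial:
    def test_row_count_audit(self, small_noise_free_trial):
        design, table = small_noise_free_trial
        n_sub = 2 * design.n_per_arm
        # plasma: (1 baseline + 3 during) x 2 phases
        plasma = table.readings[table.readings["channel_set"] == en.GLUCOSE_CHANNEL]
        assert len(plasma) == n_sub * 8
        dna = table.readings[table.readings["channel_set"] == en.DNA_CHANNEL]
        blood_dna = dna[dna["compartment"] == "blood"]
        # per phase: (1 baseline + 4 post-label days) x 2 cell types
        assert len(blood_dna) == n_sub * 2 * 5 * 2
        sputum_dna = dna[dna["compartment"] == "sputum"]
        assert len(sputum_dna) == n_sub * 3  # 2 in phase 1 + 1 in phase 2

    def test_two_arms_with_n_subjects_each(self, small_noise_free_trial):
        design, table = small_noise_free_trial
        arms = table.counts.groupby("arm")["subject_id"].nunique()
        assert arms["placebo"] == design.n_per_arm
        assert arms["mepolizumab"] == design.n_per_arm

    def test_baseline_counts_respect_inclusion_floor(self):
        design = syn.default_design(seed=1)
        table = syn.generate_trial(design, master_seed=123)
        base = table.counts[
            (table.counts["cell_type"] == "eosinophil")
            & (table.counts["compartment"] == "blood")
            & (table.counts["study_day"] < 0)
            & (table.counts["phase"] == 1)
        ]
        # measured baselines are noisy; the underlying profile floor is 0.25,
        # verified via the noise-free value reconstruction
        nf = syn.generate_trial(
            design,
            scenario=dataclasses.replace(
                syn.TreatmentScenario(), count_noise_cv=0.0
            ),
            master_seed=123,
        )
        base_nf = nf.counts[
            (nf.counts["cell_type"] == "eosinophil")
            & (nf.counts["compartment"] == "blood")
            & (nf.counts["study_day"] < 0)
            & (nf.counts["phase"] == 1)
        ]
        assert (base_nf["value"] >= 0.25).all()
        assert len(base) == len(base_nf)

    def test_truth_sidecar_is_separate_from_measurements(self, small_noise_free_trial):
        _, table = small_noise_free_trial
        assert "true_normalized_enrichment" not in table.readings.columns
        assert "area_m0" not in table.truth.columns

    def test_placebo_landmarks_reproduced_in_truth(self, small_noise_free_trial):
        """Blood peak near day 6-7, sputum maximum lower than blood."""
        _, table = small_noise_free_trial
        t = table.truth
        eos = t[(t["arm"] == "placebo") & (t["cell_type"] == "eosinophil") & (t["phase"] == 1)]
        blood = eos[eos["compartment"] == "blood"]
        by_day = blood.groupby("study_day")["true_normalized_enrichment"].median()
        assert 5 <= by_day.idxmax() <= 8
        sputum = eos[eos["compartment"] == "sputum"]
        if len(sputum):
            assert (
                sputum["true_normalized_enrichment"].max()
                < blood["true_normalized_enrichment"].max()
            )
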