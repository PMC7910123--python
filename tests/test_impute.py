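"""Imputation: masking protocol, autoencoder, baselines, NRMSE."""

import numpy as np
import pytest

from rnnlr.impute import (AutoencoderImputer, ImputerConfig, MaskHoldout,
                          cohort_lab_matrix, fit_autoencoder_imputer, impute,
                          knn_impute, mask_lab_values, mean_impute, nrmse)
from rnnlr.schema import ClinicalRecord, Cohort, validate_cohort
from rnnlr.simulate import SimConfig, generate_cohort

from conftest import make_patient, quick_imputer_config


def _count_observed(cohort):
    return sum(len(r.labs) for p in cohort.patients for r in p.records)


class TestMasking:
    def test_exact_holdout_count(self, medium_cohort):
        cohort, _ = medium_cohort
        n_obs = _count_observed(cohort)
        hold = mask_lab_values(cohort, 0.2, seed=1)
        assert len(hold.holdout) == round(0.2 * n_obs)
        assert _count_observed(hold.cohort) == n_obs - len(hold.holdout)

    def test_masked_cells_were_observed_and_truth_recorded(self, small_cohort):
        cohort, _ = small_cohort
        hold = mask_lab_values(cohort, 0.3, seed=2)
        by_id = {p.patient_id: p for p in cohort.patients}
        for pid, ri, nm, truth in hold.holdout:
            assert by_id[pid].records[ri].labs[nm] == truth

    def test_determinism_per_seed(self, small_cohort):
        cohort, _ = small_cohort
        h1 = mask_lab_values(cohort, 0.2, seed=3)
        h2 = mask_lab_values(cohort, 0.2, seed=3)
        assert h1.holdout == h2.holdout
        assert mask_lab_values(cohort, 0.2, seed=4).holdout != h1.holdout

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.1])
    def test_fraction_bounds(self, small_cohort, fraction):
        with pytest.raises(ValueError):
            mask_lab_values(small_cohort[0], fraction, seed=0)

    def test_empty_observed_domain_is_an_error(self, panel):
        p = make_patient("P0", 1)
        p.records = [ClinicalRecord(0, {})]
        with pytest.raises(ValueError, match="no observed"):
            mask_lab_values(Cohort([p], panel), 0.2, seed=0)


class TestAutoencoder:
    def test_determinism(self, small_cohort):
        cohort, _ = small_cohort
        cfg = quick_imputer_config()
        a = impute(fit_autoencoder_imputer(cohort, cfg), cohort)
        b = impute(fit_autoencoder_imputer(cohort, cfg), cohort)
        ma, _ = cohort_lab_matrix(a)
        mb, _ = cohort_lab_matrix(b)
        assert np.array_equal(ma, mb)

    def test_observed_cells_preserved_and_all_filled(self, small_cohort):
        cohort, _ = small_cohort
        out = impute(fit_autoencoder_imputer(cohort, quick_imputer_config()),
                     cohort)
        for p_in, p_out in zip(cohort.patients, out.patients):
            for r_in, r_out in zip(p_in.records, p_out.records):
                assert len(r_out.labs) == len(cohort.panel)
                for nm, v in r_in.labs.items():
                    assert r_out.labs[nm] == v

    def test_imputed_values_within_panel_ranges(self, small_cohort):
        cohort, _ = small_cohort
        out = impute(fit_autoencoder_imputer(cohort, quick_imputer_config()),
                     cohort)
        assert validate_cohort(out) == []

    def test_no_missing_cells_is_identity(self, small_cohort):
        cohort, _ = small_cohort
        full = mean_impute(cohort)
        out = impute(fit_autoencoder_imputer(full, quick_imputer_config()),
                     full)
        m1, _ = cohort_lab_matrix(full)
        m2, _ = cohort_lab_matrix(out)
        assert np.array_equal(m1, m2)

    def test_correlated_analytes_beat_mean_imputer(self):
        """With cross-analyte structure the reconstruction must use it:
        autoencoder error < mean-imputer error on the same mask."""
        cohort, _ = generate_cohort(SimConfig(
            n_patients=400, missing_rate=0.0, seed=6,
            prevalence=(0.7, 0.12, 0.18)))
        hold = mask_lab_values(cohort, 0.2, seed=6)
        ae = impute(fit_autoencoder_imputer(
            hold.cohort, ImputerConfig(seed=6)), hold.cohort)
        assert nrmse(ae, hold, cohort) < nrmse(mean_impute(hold.cohort),
                                               hold, cohort)

    def test_panel_mismatch_rejected(self, small_cohort, panel):
        cohort, _ = small_cohort
        imp = fit_autoencoder_imputer(cohort, quick_imputer_config())
        other = Cohort(cohort.patients, panel[:-1])
        with pytest.raises(ValueError, match="panel"):
            impute(imp, other)

    def test_symmetric_widths(self):
        imp = AutoencoderImputer(ImputerConfig(hidden=(32, 16)))
        assert imp._widths(18) == [18, 32, 16, 32, 18]


class TestBaselines:
    def test_mean_impute_uses_other_records(self, panel):
        a = make_patient("P0", 1, labs={"albumin": 2.0, "creatinine": 1.0})
        b = make_patient("P1", 1, labs={"albumin": 4.0, "creatinine": 2.0})
        c = make_patient("P2", 1, labs={"creatinine": 3.0})  # albumin missing
        out = mean_impute(Cohort([a, b, c], panel))
        assert out.patients[2].records[0].labs["albumin"] == pytest.approx(3.0)

    def test_knn_exact_duplicate_with_k1(self, panel):
        labs = {a.name: a.midpoint for a in panel}
        donor = make_patient("P0", 1, labs=dict(labs))
        # identical record with albumin removed; far-away third record
        focal_labs = dict(labs)
        del focal_labs["albumin"]
        focal = make_patient("P1", 1, labs=focal_labs)
        far = make_patient("P2", 1, labs={
            a.name: a.valid_range[1] for a in panel})
        out = knn_impute(Cohort([donor, focal, far], panel), k=1)
        assert out.patients[1].records[0].labs["albumin"] == \
            pytest.approx(labs["albumin"])

    def test_knn_with_large_k_is_donor_mean(self, panel):
        labs1 = {a.name: a.valid_range[0] for a in panel}
        labs2 = {a.name: a.valid_range[1] for a in panel}
        focal_labs = {a.name: a.midpoint for a in panel}
        del focal_labs["albumin"]
        cohort = Cohort([make_patient("P0", 1, labs=labs1),
                         make_patient("P1", 1, labs=labs2),
                         make_patient("P2", 1, labs=focal_labs)], panel)
        out = knn_impute(cohort, k=99)
        expected = 0.5 * (labs1["albumin"] + labs2["albumin"])
        assert out.patients[2].records[0].labs["albumin"] == \
            pytest.approx(expected)

    def test_knn_without_complete_cases_falls_back_to_mean(self, panel):
        a = make_patient("P0", 1, labs={"albumin": 2.0})
        b = make_patient("P1", 1, labs={"albumin": 4.0, "creatinine": 1.0})
        with pytest.warns(UserWarning, match="complete"):
            out = knn_impute(Cohort([a, b], panel), k=1)
        assert out.patients[0].records[0].labs["creatinine"] == \
            pytest.approx(1.0)


class TestNRMSE:
    def _single_analyte_setup(self, panel, truths, imputations):
        ref_patients = [make_patient(f"R{i}", 1, labs={"albumin": t})
                        for i, t in enumerate(truths)]
        reference = Cohort(ref_patients, panel)
        imp_patients = [make_patient(f"R{i}", 1, labs={"albumin": v})
                        for i, v in enumerate(imputations)]
        imputed = Cohort(imp_patients, panel)
        holdout = MaskHoldout(imputed, [
            (f"R{i}", 0, "albumin", t) for i, t in enumerate(truths)])
        return imputed, holdout, reference

    def test_hand_computed_example(self, panel):
        # truths {4, 6}, imputations {5, 5}, reference mean 5 -> 1/5
        imputed, holdout, reference = self._single_analyte_setup(
            panel, [4.0, 6.0], [5.0, 5.0])
        assert nrmse(imputed, holdout, reference) == pytest.approx(0.2)

    def test_perfect_imputation_scores_zero(self, panel):
        imputed, holdout, reference = self._single_analyte_setup(
            panel, [4.0, 6.0], [4.0, 6.0])
        assert nrmse(imputed, holdout, reference) == 0.0

    def test_scale_invariance(self, panel):
        a = self._single_analyte_setup(panel, [1.0, 2.0], [1.5, 1.5])
        b = self._single_analyte_setup(panel, [10.0, 20.0], [15.0, 15.0])
        assert nrmse(*a) == pytest.approx(nrmse(*b))

    def test_unfilled_holdout_cell_is_an_error(self, panel):
        imputed, holdout, reference = self._single_analyte_setup(
            panel, [4.0, 6.0], [5.0, 5.0])
        del imputed.patients[0].records[0].labs["albumin"]
        with pytest.raises(ValueError, match="not imputed"):
            nrmse(imputed, holdout, reference)
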