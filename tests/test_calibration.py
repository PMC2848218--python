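"""Calibration from depletion-imaging occupancies and synthetic studies."""

import numpy as np
import pytest

from frontostriatal import (
    DomainError,
    InfeasibleError,
    OccupancyRecord,
    average_hc_occupancy,
    build_model,
    efficacy_and_pfc_from_model,
    estimate_da_from_bp_increase,
    extrapolate_sz_occupancy,
    generate_synthetic_depletion_study,
    load_occupancy_table,
    model_1,
    model_2,
    sz_hc_differences,
)


class TestOccupancyTable:
    def test_packaged_table_reproduces_hc_average(self):
        records = load_occupancy_table()
        assert average_hc_occupancy(records) == pytest.approx(0.236, abs=1e-12)

    def test_single_record_average(self):
        assert average_hc_occupancy([OccupancyRecord("s", "HC", 0.12)]) == 0.12

    def test_all_sz_input_errors(self):
        with pytest.raises(DomainError):
            average_hc_occupancy([OccupancyRecord("s", "SZ", 0.21)])

    def test_missing_cells_skipped_not_zero(self):
        records = [
            OccupancyRecord("a", "HC", 0.2),
            OccupancyRecord("b", "HC", None),
            OccupancyRecord("c", "HC", 0.4),
        ]
        assert average_hc_occupancy(records) == pytest.approx(0.3)

    def test_out_of_range_occupancy_rejected_with_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "study_label,cohort,occupancy_percent\nok,HC,12\nbad,HC,105\n"
        )
        with pytest.raises(DomainError, match="row 1"):
            load_occupancy_table(p)

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("study,occ\nx,1\n")
        with pytest.raises(DomainError):
            load_occupancy_table(p)


class TestExtrapolation:
    def test_hc_average_extrapolates_to_patient_occupancy(self, m1):
        assert extrapolate_sz_occupancy(0.236, m1) == pytest.approx(0.413, abs=5e-4)

    def test_self_consistency_with_reference_ratio(self, m1):
        assert extrapolate_sz_occupancy(0.12, m1) == pytest.approx(0.21, abs=1e-12)

    def test_unit_ratio_is_identity(self):
        unit = build_model(0.3, 0.3, b_max_sz=1.0)
        assert extrapolate_sz_occupancy(0.17, unit) == pytest.approx(0.17)


class TestBuildModel:
    def test_model_1_normalized_da_levels(self, m1):
        assert m1.hc.b_max == 1.0 and m1.sz.b_max == 1.2
        assert round(m1.hc.y, 3) == 0.136
        assert round(m1.sz.y, 3) == 0.266
        assert round(m1.hc.occupancy, 2) == 0.12
        assert round(m1.sz.occupancy, 2) == 0.21

    def test_model_2_normalized_da_levels(self, m2):
        assert m2.hc.b_max == 1.0 and m2.sz.b_max == 1.2
        assert round(m2.hc.y, 3) == 0.316
        assert round(m2.sz.y, 3) == 0.695
        assert round(m2.hc.occupancy, 2) == 0.24
        assert round(m2.sz.occupancy, 2) == 0.41

    def test_zero_occupancy_model(self):
        m = build_model(0.0, 0.0, b_max_sz=1.0)
        assert m.hc.y == 0.0 and m.sz.y == 0.0

    def test_invalid_occupancy_rejected(self):
        with pytest.raises(DomainError):
            build_model(1.0, 0.2, b_max_sz=1.0)


class TestEfficacyAndPfc:
    def test_no_d2_modulation_gives_drive_minus_release(self, m1):
        res = efficacy_and_pfc_from_model(m1, a=0.0, b=0.0)
        assert res["HC"][1] == pytest.approx(1.0 - m1.hc.y, abs=1e-12)
        assert res["HC"][1] == pytest.approx(0.864, abs=1e-3)
        assert res["SZ"][1] == pytest.approx(0.734, abs=1e-3)
        # hypofrontality: patient PFC activity is lower
        assert res["SZ"][1] - res["HC"][1] == pytest.approx(-0.130, abs=1e-3)

    def test_no_heteroreceptor_means_unit_efficacy(self, m1, m2):
        for m in (m1, m2):
            res = efficacy_and_pfc_from_model(m, a=0.3, b=0.0)
            assert res["HC"][0] == 1.0 and res["SZ"][0] == 1.0

    def test_density_scaling_amplifies_patient_d2_effect(self, m1):
        scaled = efficacy_and_pfc_from_model(m1, a=0.0, b=1.0, scale_by_density=True)
        raw = efficacy_and_pfc_from_model(m1, a=0.0, b=1.0, scale_by_density=False)
        assert scaled["SZ"][0] < raw["SZ"][0]
        assert scaled["HC"][0] == raw["HC"][0]  # HC density is 1

    def test_infeasible_when_modulation_saturates(self):
        strong = build_model(0.6, 0.8, b_max_sz=1.2)
        with pytest.raises(InfeasibleError):
            efficacy_and_pfc_from_model(strong, a=0.0, b=1.3)


class TestSzHcDifferences:
    def test_efficacy_difference_independent_of_autoreceptor(self, m1):
        df = sz_hc_differences(m1, a_values=[0.0, 0.2, 0.4], b_grid=np.linspace(0, 1, 11))
        pivot = df.pivot(index="b", columns="a", values="delta_v_ps")
        cols = pivot.to_numpy()
        # bitwise identical across a at every b
        assert np.all(cols[:, 0] == cols[:, 1])
        assert np.all(cols[:, 0] == cols[:, 2])

    def test_pfc_difference_depends_on_autoreceptor(self, m1):
        df = sz_hc_differences(m1, a_values=[0.0, 0.4], b_grid=[0.5])
        vals = df["delta_x_p"].to_numpy()
        assert vals[0] != vals[1]

    def test_no_heteroreceptor_column_is_zero(self, m1):
        df = sz_hc_differences(m1, a_values=[0.0, 0.2, 0.4], b_grid=[0.0])
        assert np.all(df["delta_v_ps"].to_numpy() == 0.0)

    def test_model_2_shows_stronger_hypofrontality(self, m1, m2):
        d1 = sz_hc_differences(m1, a_values=[0.0], b_grid=[0.0])["delta_x_p"].item()
        d2 = sz_hc_differences(m2, a_values=[0.0], b_grid=[0.0])["delta_x_p"].item()
        assert d1 == pytest.approx(-0.130, abs=1e-3)
        assert d2 == pytest.approx(-0.379, abs=1e-3)
        assert abs(d2) > abs(d1)


class TestSyntheticDepletion:
    def test_noiseless_observations_recover_truth_exactly(self):
        obs = generate_synthetic_depletion_study(0.266, alpha=0.3, n_subjects=5, seed=0)
        for o in obs:
            assert estimate_da_from_bp_increase(o.beta, 0.3) == pytest.approx(
                0.266, abs=1e-12
            )

    def test_seed_determinism(self):
        a = generate_synthetic_depletion_study(0.3, noise_cv=0.1, n_subjects=10, seed=7)
        b = generate_synthetic_depletion_study(0.3, noise_cv=0.1, n_subjects=10, seed=7)
        assert [(o.bp_baseline, o.bp_depleted) for o in a] == [
            (o.bp_baseline, o.bp_depleted) for o in b
        ]

    @staticmethod
    def _recovered(obs, alpha=0.3):
        return np.array(
            [estimate_da_from_bp_increase(max(o.beta, 0.0), alpha) for o in obs]
        )

    def test_mean_recovery_within_three_standard_errors(self):
        obs = generate_synthetic_depletion_study(
            0.266, alpha=0.3, n_subjects=50, noise_cv=0.05, seed=11
        )
        est = self._recovered(obs)
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - 0.266) < 3 * se

    def test_error_shrinks_with_noise_level(self):
        true_y = 0.266
        maes = []
        for cv in (0.1, 0.05, 0.01):
            obs = generate_synthetic_depletion_study(
                true_y, alpha=0.3, n_subjects=200, noise_cv=cv, seed=5
            )
            est = self._recovered(obs)
            maes.append(np.median(np.abs(est - true_y)))
        assert maes[0] > maes[1] > maes[2]

    def test_error_shrinks_with_sample_size(self):
        true_y = 0.266
        errs = []
        for n in (10, 100, 1000):
            obs = generate_synthetic_depletion_study(
                true_y, alpha=0.3, n_subjects=n, noise_cv=0.1, seed=9
            )
            errs.append(abs(self._recovered(obs).mean() - true_y))
        assert errs[2] < errs[0]

    def test_parameter_validation(self):
        with pytest.raises(DomainError):
            generate_synthetic_depletion_study(0.3, noise_cv=-0.1)
        with pytest.raises(DomainError):
            generate_synthetic_depletion_study(0.3, n_subjects=0)
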