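"""Synthetic cohort generator: construction contracts and planted effects."""

import numpy as np
import pandas as pd
import pytest

from tractfa import phantom
from tractfa.tensor import compute_fa

from conftest import fa_oracle


class TestGradientTable:
    def test_protocol_counts_and_b(self):
        for n in (31, 65):
            gt = phantom.protocol_gradient_table(n)
            assert len(gt.b_values) == n
            assert np.sum(gt.b_values == 0) == 1
            assert np.all(gt.b_values[gt.b_values > 0] == 1000.0)

    def test_validation_rejects_bad_tables(self):
        dirs = np.vstack([np.zeros(3), np.eye(3)])
        with pytest.raises(ValueError, match="b=0"):
            phantom.GradientTable(dirs, np.array([0.0, 0.0, 1000.0, 1000.0]))
        with pytest.raises(ValueError, match="unit"):
            phantom.GradientTable(
                np.vstack([np.zeros(3), [[2, 0, 0], [0, 1, 0], [0, 0, 1]]]),
                np.array([0.0, 1000.0, 1000.0, 1000.0]))

    def test_bvec_bval_roundtrip(self, tmp_path):
        gt = phantom.protocol_gradient_table(31)
        gt.save(tmp_path / "protocol")
        back = phantom.GradientTable.load(tmp_path / "protocol")
        assert np.allclose(back.directions, gt.directions, atol=1e-7)
        assert np.allclose(back.b_values, gt.b_values)


class TestTensorFieldConstruction:
    def test_background_is_isotropic_with_zero_fa(self, spec, control_field):
        fa = compute_fa(control_field).data
        support = phantom.geometry(spec).support_mask()
        assert fa[~support].max() == 0.0

    def test_tube_fa_matches_designed_eigenvalues(self, spec, control_field):
        """Generated tube tensors reproduce the closed-form FA to 1e-12."""
        fa = compute_fa(control_field).data
        tube = phantom.geometry(spec).tract_mask("cc_ii")
        designed = fa_oracle([1.7e-3, 0.3e-3, 0.3e-3])
        assert np.abs(fa[tube] - designed).max() < 1e-12

    def test_lesion_reduces_fa_by_planted_amount(self, spec, cohort):
        row = cohort[cohort.group == "nfppa"].iloc[0]
        field = phantom.build_tensor_field(spec, row)
        fa = compute_fa(field).data
        geom = phantom.geometry(spec)
        les = geom.lesion_mask(spec.lesions[0])
        depth = phantom.lesion_depth(spec, row)
        base_fa = fa_oracle([1.7e-3, 0.3e-3, 0.3e-3])
        assert np.abs(fa[les] - (base_fa - depth)).max() < 1e-9
        # outside the lesion the tube keeps its design FA
        tube = geom.tract_mask("cc_ii") & ~les
        assert np.abs(fa[tube] - base_fa).max() < 1e-12

    def test_followup_lesion_is_deeper_and_longer(self, spec, cohort):
        row = cohort[cohort.group == "svppa"].iloc[0]
        fa0 = phantom.ground_truth_fa(spec, row, "baseline").data
        fa1 = phantom.ground_truth_fa(spec, row, "followup").data
        geom = phantom.geometry(spec)
        tube = geom.tract_mask("left_ilf")
        assert fa1[tube].min() < fa0[tube].min()          # deeper
        assert (fa1 < fa0 - 1e-9).sum() > 0               # progressed voxels
        m0 = geom.lesion_mask(spec.lesions[1])
        m1 = geom.lesion_mask(spec.lesions[1], progression=spec.followup_progression)
        assert m1.sum() > m0.sum()                        # longer span

    def test_tract_leaving_grid_rejected(self):
        tract = phantom.TractGeometry("runaway",
                                      [(-100, 0, 0), (100, 0, 0)], radius=4.0)
        spec = phantom.default_spec(seed=0, tracts=[tract], lesions=[])
        with pytest.raises(ValueError, match="leaves the grid"):
            phantom.PhantomGeometry(spec)

    def test_determinism_bit_identical(self, spec, control_row):
        a = phantom.build_tensor_field(spec, control_row)
        b = phantom.build_tensor_field(spec, control_row)
        assert np.array_equal(a.data, b.data)
        fa_a = phantom.sample_fa_map(spec, control_row)
        fa_b = phantom.sample_fa_map(spec, control_row)
        assert np.array_equal(fa_a.data, fa_b.data)


class TestSimulateDwi:
    def test_b0_volume_is_s0(self, control_field):
        gtab = phantom.protocol_gradient_table(13)
        dwi = phantom.simulate_dwi(control_field, gtab, s0=777.0)
        assert np.allclose(dwi[..., 0], 777.0)

    def test_isotropic_unit_trace_attenuation(self):
        """Isotropic D with trace 3e-3 attenuates to s0/e at b=1000 for any g."""
        from tractfa.grids import TensorField
        data = np.zeros((1, 1, 1, 6))
        data[..., [0, 3, 5]] = 1e-3
        field = TensorField(data, np.eye(4))
        gtab = phantom.protocol_gradient_table(13)
        dwi = phantom.simulate_dwi(field, gtab, s0=1000.0)
        assert np.allclose(dwi[0, 0, 0, 1:], 1000.0 * np.exp(-1.0), rtol=1e-12)

    def test_perpendicular_to_parallel_ratio(self, spec, control_field):
        """S_perp/S_par = exp(-b (lambda_perp - lambda_par)) on a tube voxel."""
        geom = phantom.geometry(spec)
        vox = np.argwhere(geom.tract_mask("cc_ii"))[50]
        g_par = np.array([1.0, 0, 0])          # cc_ii runs along x
        g_perp = np.array([0, 0, 1.0])
        dirs = np.vstack([np.zeros(3), g_par, g_perp])
        gtab = phantom.GradientTable(dirs, np.array([0.0, 1000.0, 1000.0]))
        dwi = phantom.simulate_dwi(control_field, gtab, s0=100.0)
        ratio = dwi[tuple(vox)][2] / dwi[tuple(vox)][1]
        expected = np.exp(-1000.0 * (0.3e-3 - 1.7e-3))
        assert ratio == pytest.approx(expected, rel=1e-9)

    def test_negative_s0_rejected(self, control_field):
        gtab = phantom.protocol_gradient_table(13)
        with pytest.raises(ValueError, match="s0"):
            phantom.simulate_dwi(control_field, gtab, s0=-5.0)


class TestScores:
    def test_controls_score_zero(self, cohort):
        assert (cohort.loc[cohort.group == "control", "ftld_cdr_sob"] == 0).all()

    def test_noiseless_scores_follow_depth_exactly(self, spec):
        quiet = phantom.default_spec(seed=3, groups=spec.groups,
                                     followup_groups={},
                                     score_model=phantom.ScoreModel(noise_sd=0.0))
        coh = phantom.assign_scores(quiet, phantom.make_cohort(quiet))
        pat = coh[(coh.group == "nfppa") & (coh.timepoint == "baseline")]
        depths = np.array([phantom.lesion_depth(quiet, r) for _, r in pat.iterrows()])
        r = np.corrcoef(depths, pat["ftld_cdr_sob"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_designed_score_correlation_near_minus_07(self):
        """At a lesion voxel, FA vs score correlates near the designed -0.7
        (Monte-Carlo with a large synthetic patient group)."""
        big = phantom.default_spec(
            seed=9, groups=[("nfppa", 1000, 60.4, 5.0)], followup_groups={},
            center_a_fraction={"nfppa": 1.0})
        coh = phantom.assign_scores(big, phantom.make_cohort(big))
        depths = np.array([phantom.lesion_depth(big, r) for _, r in coh.iterrows()])
        fa_at_lesion = 0.799 - depths       # exact construction at a lesion voxel
        r = np.corrcoef(fa_at_lesion, coh["ftld_cdr_sob"])[0, 1]
        assert r == pytest.approx(-0.7, abs=0.05)

    def test_all_control_cohort_scores_zero(self):
        ctl_only = phantom.default_spec(seed=2,
                                        groups=[("control", 10, 58.0, 10.0)],
                                        followup_groups={})
        coh = phantom.assign_scores(ctl_only, phantom.make_cohort(ctl_only))
        assert (coh["ftld_cdr_sob"] == 0).all()


class TestComponentMaps:
    def test_probability_sum_bounded(self, spec, control_row):
        gm, wm, csf, _ = phantom.build_component_maps(spec, control_row)
        total = gm.data + wm.data + csf.data
        assert total.max() <= 1.0 + 1e-12
        assert gm.data.min() >= 0.0

    def test_planted_atrophy_scales_integrated_volume(self, spec, cohort):
        """GM volume in the atrophied label shrinks by the planted factor."""
        from tractfa.volumetry import integrate_soi
        row = cohort[cohort.group == "nfppa"].iloc[0].copy()
        quiet = phantom.default_spec(seed=spec.seed, groups=spec.groups,
                                     followup_groups={}, atrophy_noise_sd=0.0,
                                     head_size_sd=0.0)
        ctl = row.copy()
        ctl["group"] = "control"
        gm_pat, *_, atlas = phantom.build_component_maps(quiet, row)
        gm_ctl, *_ , _ = phantom.build_component_maps(quiet, ctl)
        vols_pat = integrate_soi(gm_pat, atlas, phantom.SOI_LABELS)
        vols_ctl = integrate_soi(gm_ctl, atlas, phantom.SOI_LABELS)
        loss = (1 - 0.85) * float(row["severity"])
        assert vols_pat["left_frontal"] == pytest.approx(
            vols_ctl["left_frontal"] * (1 - loss), rel=1e-9)
        assert vols_pat["right_frontal"] == pytest.approx(
            vols_ctl["right_frontal"], rel=1e-9)


def test_truth_summary_consistent(spec, cohort):
    truth = phantom.truth_summary(spec, cohort)
    geom = phantom.geometry(spec)
    assert truth["tract_voxel_counts"]["cc_ii"] == int(geom.tract_mask("cc_ii").sum())
    key = f"{cohort.iloc[0]['subject_id']}@baseline"
    assert truth["per_subject"][key]["lesion_depth"] == 0.0  # first subject is a control


def test_cohort_dataset_written(tmp_path, spec):
    small = phantom.default_spec(seed=1, groups=[("control", 2, 58, 5),
                                                 ("nfppa", 2, 60, 5)],
                                 followup_groups={})
    coh = phantom.generate_cohort_dataset(small, tmp_path)
    assert (tmp_path / "cohort.tsv").exists()
    assert (tmp_path / "truth.json").exists()
    table = pd.read_csv(tmp_path / "cohort.tsv", sep="\t")
    assert set(table.columns) >= {"subject_id", "group", "age", "sex", "center",
                                  "timepoint", "mmse", "ftld_cdr_sob"}
    assert len(list(tmp_path.glob("*_fa.nii.gz"))) == len(coh)
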