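"""Seed-to-target streamline tracking and tract-wise FA statistics."""

import numpy as np
import pandas as pd
import pytest

from tractfa import phantom, tracking
from tractfa.grids import ScalarMap, default_affine
from tractfa.tensor import compute_fa


@pytest.fixture(scope="module")
def template(spec, cohort):
    ctl = cohort[cohort.group == "control"].head(2)
    fields = [phantom.build_tensor_field(spec, r) for _, r in ctl.iterrows()]
    return tracking.average_tensor_template(fields)


@pytest.fixture(scope="module")
def tois(spec, template):
    return {t.name: t for t in
            tracking.phantom_toi_definitions(spec, compute_fa(template))}


def _curved_tube_spec(seed=0):
    """Quarter-circle tube of radius 24 mm centred near the grid middle."""
    theta = np.linspace(0, np.pi / 2, 60)
    R = 24.0
    line = np.stack([R * np.cos(theta) - 12, R * np.sin(theta) - 12,
                     np.zeros_like(theta)], axis=1)
    tract = phantom.TractGeometry("arc", line, radius=5.0)
    return phantom.default_spec(seed=seed, tracts=[tract], lesions=[],
                                atrophy=[]), R * np.pi / 2


class TestAverageTemplate:
    def test_identical_inputs_reproduce_input(self, spec, control_field):
        out = tracking.average_tensor_template([control_field, control_field])
        assert np.array_equal(out.data, control_field.data)

    def test_mean_principal_axis_bisects_rotated_pair(self):
        """Two tensors rotated +/- theta about z average to their bisector."""
        lam = np.diag([1.7e-3, 0.3e-3, 0.3e-3])
        out_mats = []
        for sgn in (1, -1):
            th = sgn * np.deg2rad(20)
            Rz = np.array([[np.cos(th), -np.sin(th), 0],
                           [np.sin(th), np.cos(th), 0], [0, 0, 1]])
            out_mats.append(Rz @ lam @ Rz.T)
        from tractfa.grids import TensorField
        fields = [TensorField.from_matrices(m[None, None, None], np.eye(4))
                  for m in out_mats]
        mean = tracking.average_tensor_template(fields)
        # independent eigen-decomposition oracle
        M = (out_mats[0] + out_mats[1]) / 2
        w, v = np.linalg.eigh(M)
        e1 = v[:, 2]
        got_w, got_v = mean.eigensystem()
        assert np.abs(np.abs(got_v[0, 0, 0][:, 2] @ e1) - 1.0) < 1e-12
        assert abs(abs(e1[0]) - 1.0) < 1e-12     # bisector is the x axis

    def test_trace_linearity(self, spec, cohort):
        rows = cohort[cohort.group == "control"].head(3)
        fields = [phantom.build_tensor_field(spec, r) for _, r in rows.iterrows()]
        mean = tracking.average_tensor_template(fields)
        traces = [f.data[..., [0, 3, 5]].sum(-1) for f in fields]
        assert np.abs(mean.data[..., [0, 3, 5]].sum(-1)
                      - np.mean(traces, axis=0)).max() < 1e-15


class TestTrack:
    def test_straight_tube_retains_nearly_all_launches(self, template, tois):
        params = tracking.TrackingParams(perturbation_deg=0.0)
        res = tracking.track(template, tois["cc_ii"], params, seed=0)
        assert res.n_launched > 0
        assert res.n_retained / res.n_launched >= 0.95

    def test_visitation_confined_to_dilated_tube(self, spec, template, tois):
        from scipy.ndimage import binary_dilation
        res = tracking.track(template, tois["cc_ii"], seed=0)
        tube = phantom.geometry(spec).tract_mask("cc_ii")
        allowed = binary_dilation(tube, iterations=1)
        assert not (res.tract_mask() & ~allowed).any()

    def test_seed_in_low_fa_background_yields_no_streamlines(self, spec, template):
        seed = np.zeros(spec.grid_shape, dtype=bool)
        seed[2:4, 2:4, 2:4] = True       # isotropic background, FA = 0
        target = np.zeros_like(seed)
        target[-4:-2, -4:-2, -4:-2] = True
        toi = tracking.TOIDefinition("bg", seed, target)
        res = tracking.track(template, toi, seed=0)
        assert res.n_retained == 0
        assert res.visitation.data.sum() == 0

    def test_curved_tube_lengths_match_arc_geometry(self):
        spec, arc_len = _curved_tube_spec()
        cohort = phantom.make_cohort(spec)
        field = phantom.build_tensor_field(spec, cohort.iloc[0])
        fa_map = compute_fa(field)
        toi = tracking.phantom_toi_definitions(spec, fa_map)[0]
        params = tracking.TrackingParams(max_angle_deg=30.0, step_mm=1.0,
                                         perturbation_deg=0.0)
        res = tracking.track(field, toi, params, seed=0)
        assert res.n_retained > 0
        # geometry oracle: each retained streamline should cover the arc from
        # its start position to the target-sphere entry (inset 6 mm + radius 6 mm)
        theta = np.linspace(0, np.pi / 2, 2000)
        dense = np.stack([24 * np.cos(theta) - 12, 24 * np.sin(theta) - 12,
                          np.zeros_like(theta)], axis=1)
        arcs = np.linspace(0, arc_len, 2000)
        ratios = []
        for s in res.streamlines:
            length = np.sum(np.linalg.norm(np.diff(s, axis=0), axis=1))
            s0 = arcs[np.argmin(np.linalg.norm(dense - s[0], axis=1))]
            expected = (arc_len - 12.0) - s0
            if expected > 5.0:
                ratios.append(length / expected)
        assert np.median(ratios) == pytest.approx(1.0, abs=0.10)

    def test_fixed_seed_reproducible(self, template, tois):
        a = tracking.track(template, tois["left_ilf"], seed=5)
        b = tracking.track(template, tois["left_ilf"], seed=5)
        assert a.n_retained == b.n_retained
        assert np.array_equal(a.visitation.data, b.visitation.data)
        for s1, s2 in zip(a.streamlines, b.streamlines):
            assert np.array_equal(s1, s2)

    def test_toi_validation(self, spec):
        full = np.ones(spec.grid_shape, dtype=bool)
        with pytest.raises(ValueError, match="overlap"):
            tracking.TOIDefinition("bad", full, full)
        with pytest.raises(ValueError, match="non-empty"):
            tracking.TOIDefinition("bad", np.zeros_like(full), full)


class TestTfas:
    def _result_with_mask(self, spec, mask):
        vis = ScalarMap(mask.astype(float), spec.affine, "mask")
        seed = np.zeros_like(mask)
        seed[0, 0, 0] = True
        target = np.zeros_like(mask)
        target[-1, -1, -1] = True
        toi = tracking.TOIDefinition("m", seed, target)
        return tracking.TOIResult(toi, [], vis)

    def test_constant_fa_on_tract(self, spec):
        mask = phantom.geometry(spec).tract_mask("cc_ii")
        res = self._result_with_mask(spec, mask)
        fa = ScalarMap(np.where(mask, 0.5, 0.0), spec.affine)
        rec = tracking.tfas(res, fa, subject_id="s1")
        assert rec.mean_fa == pytest.approx(0.5)
        assert rec.n_voxels == int(mask.sum())

    def test_half_half_mix_averages(self, spec):
        mask = phantom.geometry(spec).tract_mask("cc_ii")
        idx = np.argwhere(mask)
        vals = np.zeros(spec.grid_shape)
        half = len(idx) // 2
        vals[tuple(idx[:half].T)] = 0.4
        vals[tuple(idx[half:].T)] = 0.6
        res = self._result_with_mask(spec, mask)
        rec = tracking.tfas(res, ScalarMap(vals, spec.affine))
        assert rec.mean_fa == pytest.approx(0.5, abs=0.01)

    def test_duplicate_streamlines_do_not_change_mean(self, template, tois, spec):
        res = tracking.track(template, tois["cc_ii"], seed=1)
        doubled = tracking.TOIResult(res.toi, res.streamlines * 2,
                                     res.visitation.like(res.visitation.data * 2))
        fa = ScalarMap(np.full(spec.grid_shape, 0.42), spec.affine)
        assert tracking.tfas(res, fa).mean_fa == tracking.tfas(doubled, fa).mean_fa

    def test_group_difference_recovers_planted_delta(self, spec, cohort, toi_masks):
        """TFAS group contrast matches the designed tract-mean FA drop."""
        from tractfa import study
        fa_maps = study.generate_fa_maps(spec, cohort)
        corrected, _, _ = study.harmonize_fa_maps(spec, cohort, fa_maps)
        records = study.tfas_from_masks(toi_masks, cohort, corrected)
        labels = cohort[cohort.timepoint == "baseline"].set_index("subject_id")
        merged = records.join(labels["group"], on="subject_id")
        sub = merged[merged.toi == "cc_ii"]
        diff = (sub.loc[sub.group == "control", "mean_fa"].mean()
                - sub.loc[sub.group == "nfppa", "mean_fa"].mean())
        # designed mean drop over the tract: depth x lesioned fraction
        geom = phantom.geometry(spec)
        frac = geom.lesion_mask(spec.lesions[0]).sum() / geom.tract_mask("cc_ii").sum()
        pat = cohort[(cohort.group == "nfppa") & (cohort.timepoint == "baseline")]
        depth = np.mean([phantom.lesion_depth(spec, r) for _, r in pat.iterrows()])
        assert diff == pytest.approx(depth * frac, abs=0.02)


class TestGroupTest:
    def _records(self, means, n=10, sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for grp, mu in means.items():
            for i in range(n):
                rows.append(dict(subject_id=f"{grp}_{i:03d}", toi="t1",
                                 mean_fa=mu + rng.normal(0, sd), n_voxels=100))
        return pd.DataFrame(rows)

    def _cohort(self, groups, n=10):
        rows = [dict(subject_id=f"{g}_{i:03d}", group=g, timepoint="baseline")
                for g in groups for i in range(n)]
        return pd.DataFrame(rows)

    def test_identical_groups_not_significant(self):
        rec = self._records({"nfppa": 0.5, "control": 0.5}, sd=0.01)
        out = tracking.tfas_group_test(rec, self._cohort(["nfppa", "control"]),
                                       "nfppa", "control")
        assert not out["significant"].any()

    def test_single_subject_group_rejected(self):
        rec = self._records({"nfppa": 0.4, "control": 0.5}, n=1, sd=0.01)
        with pytest.raises(ValueError, match=">=2 subjects"):
            tracking.tfas_group_test(rec, self._cohort(["nfppa", "control"], n=1),
                                     "nfppa", "control")
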