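"""Anthropometric scaling: factor arithmetic, muscle laws, percentiles."""

import numpy as np
import pytest

from anthroneck import (
    AnthropometryFeatures,
    apply_scaling,
    derive_female_model,
    generate_percentile_model,
    scale_inertia,
    segment_scale_factors,
    symmetrize,
)
from anthroneck.model import model_to_dict
from anthroneck.muscles import muscle_volume, node_char_lengths
from anthroneck.scaling import ScaleFactors, muscle_scale_factors
from anthroneck import tables


def _uniform(s: float) -> ScaleFactors:
    return ScaleFactors(neck_xy=s, neck_z=s, skull=s, torso_xy=s, torso_z=s)


class TestFactorArithmetic:
    def test_identity(self, male_model):
        f = segment_scale_factors(
            male_model.reference_anthropometry, male_model.reference_anthropometry
        )
        for name in male_model.segments:
            assert np.allclose(f.for_segment(name), 1.0, atol=1e-12)

    def test_circumference_and_length_ratios(self, male_model):
        ref = male_model.reference_anthropometry
        feats = AnthropometryFeatures(ref.height_m, ref.body_mass_kg,
                                      ref.neck_circumference_cm * 1.1,
                                      ref.neck_length_cm)
        f = segment_scale_factors(feats, ref)
        assert f.neck_xy == pytest.approx(1.1, abs=1e-12)
        assert f.neck_z == pytest.approx(1.0, abs=1e-12)

    def test_95th_male_neck_factors_from_table(self, male_model):
        row = tables.percentile_table("male").loc[95]
        feats = AnthropometryFeatures(row["stature_m"], row["body_mass_kg"],
                                      row["neck_circumference_cm"], row["neck_length_cm"])
        f = segment_scale_factors(feats, male_model.reference_anthropometry)
        assert f.neck_xy == pytest.approx(44.3 / 39.5, abs=1e-12)
        assert f.neck_z == pytest.approx(12.9 / 10.8, abs=1e-12)
        assert f.neck_xy == pytest.approx(1.1215, abs=5e-5)
        assert f.neck_z == pytest.approx(1.1944, abs=5e-5)

    def test_nonpositive_feature_rejected(self, male_model):
        with pytest.raises(ValueError):
            segment_scale_factors(
                AnthropometryFeatures(0.0, 80.0, 40.0, 11.0),
                male_model.reference_anthropometry,
            )


class TestMuscleScalingLaws:
    def test_isotropic_scale_exact_laws(self, male_model):
        s = 1.2
        scaled = apply_scaling(male_model, _uniform(s))
        for a, b in zip(scaled.fascicles, male_model.fascicles):
            assert a.f_max == pytest.approx(b.f_max * s**2, rel=1e-12)
            assert a.optimal_fiber_length == pytest.approx(
                b.optimal_fiber_length * s, rel=1e-12
            )
            assert a.tendon_slack_length == pytest.approx(
                b.tendon_slack_length * s, rel=1e-12
            )

    def test_identity_scale_is_noop(self, male_model):
        scaled = apply_scaling(male_model, _uniform(1.0))
        for a, b in zip(scaled.fascicles, male_model.fascicles):
            assert a.f_max == b.f_max
            assert np.array_equal(scaled.world_nodes(a), male_model.world_nodes(b))

    def test_anisotropic_sv_matches_direct_summation(self, male_model):
        factors = segment_scale_factors(
            AnthropometryFeatures(1.87, 110.7, 44.3, 12.9),
            male_model.reference_anthropometry,
        )
        scaled = apply_scaling(male_model, factors)
        for a, b in zip(scaled.fascicles, male_model.fascicles):
            base_pts = male_model.world_nodes(b)
            l = node_char_lengths(base_pts)
            big_l = l.sum()
            svi = np.array([
                float(np.prod(factors.for_segment(n.attached_segment)))
                for n in b.nodes
            ])
            s_v_oracle = float((l / big_l) @ svi)
            s_l = (np.linalg.norm(np.diff(scaled.world_nodes(a), axis=0), axis=1).sum()
                   / big_l)
            assert a.f_max == pytest.approx(b.f_max * s_v_oracle / s_l, rel=1e-9)

    def test_zero_length_fascicle_rejected(self):
        with pytest.raises(ValueError, match="zero length"):
            muscle_scale_factors(
                np.array([[0.0, 0, 0], [0, 0, 0.1]]),
                np.array([[0.0, 0, 0], [0, 0, 0.0]]),
                np.ones(2),
            )

    def test_round_trip_is_identity(self, male_model):
        f = segment_scale_factors(
            AnthropometryFeatures(1.87, 110.7, 44.3, 12.9),
            male_model.reference_anthropometry,
        )
        inv = ScaleFactors(neck_xy=1 / f.neck_xy, neck_z=1 / f.neck_z,
                           skull=1 / f.skull, torso_xy=1 / f.torso_xy,
                           torso_z=1 / f.torso_z)
        back = apply_scaling(apply_scaling(male_model, f), inv)
        for a, b in zip(back.fascicles, male_model.fascicles):
            assert a.f_max == pytest.approx(b.f_max, abs=1e-9)
            assert a.optimal_fiber_length == pytest.approx(
                b.optimal_fiber_length, abs=1e-9
            )
            assert np.allclose(back.world_nodes(a), male_model.world_nodes(b), atol=1e-9)
        for name in male_model.segments:
            assert back.segments[name].mass == pytest.approx(
                male_model.segments[name].mass, abs=1e-9
            )


class TestInertiaScaling:
    def test_identity(self, male_model):
        seg = scale_inertia(male_model.segments["skull"], np.ones(3))
        assert np.allclose(seg.inertia, male_model.segments["skull"].inertia)
        assert seg.mass == male_model.segments["skull"].mass

    def test_isotropic_dimensional_law(self, male_model):
        s = 1.3
        seg = scale_inertia(male_model.segments["skull"], np.full(3, s))
        base = male_model.segments["skull"]
        assert seg.mass == pytest.approx(base.mass * s**3, rel=1e-12)
        assert np.allclose(seg.inertia, base.inertia * s**5, rtol=1e-12)

    def test_affine_matches_revoxelization_for_cuboid(self):
        import trimesh
        from anthroneck import calibrate_density, label_segments, segment_inertia, voxelize
        from anthroneck.inertia import axis_plane_rules
        from anthroneck.model import Segment

        rules = axis_plane_rules([("all", np.inf)])
        a, b, c, mass = 0.2, 0.2, 0.2, 5.0
        g0 = label_segments(voxelize(trimesh.creation.box(extents=[a, b, c]), 0.01), rules)
        p0 = segment_inertia(g0, "all", calibrate_density(g0, mass))
        seg = Segment(name="s", parent_joint=None, origin=np.zeros(3),
                      mass=p0.mass, com=p0.com, inertia=p0.inertia)
        s = np.array([2.0, 1.0, 1.0])
        approx = scale_inertia(seg, s)  # density fixed: mass scales with volume
        g1 = label_segments(
            voxelize(trimesh.creation.box(extents=[2 * a, b, c]), 0.01), rules
        )
        p1 = segment_inertia(g1, "all", calibrate_density(g1, 2 * mass))
        assert approx.mass == pytest.approx(p1.mass, rel=1e-9)
        for i in range(3):
            assert approx.inertia[i, i] == pytest.approx(p1.inertia[i, i], rel=0.02)


class TestPercentiles:
    def test_50th_is_identity(self, male_model):
        p50 = generate_percentile_model(male_model, "male", 50)
        for a, b in zip(p50.fascicles, male_model.fascicles):
            assert a.f_max == pytest.approx(b.f_max, abs=1e-9)
            assert np.allclose(p50.world_nodes(a), male_model.world_nodes(b), atol=1e-9)

    def test_99th_male_neck_length_factor(self, male_model):
        p99 = generate_percentile_model(male_model, "male", 99)
        eff = p99.metadata["cumulative_scale"]["C4"]
        assert eff[2] == pytest.approx(13.8 / 10.8, abs=1e-12)
        assert eff[0] == pytest.approx(46.8 / 39.5, abs=1e-12)

    def test_unknown_percentile(self, male_model):
        with pytest.raises(ValueError, match="percentile"):
            generate_percentile_model(male_model, "male", 42)

    def test_female_circumference_factors_increase(self, female_model):
        factors = []
        for p in tables.PERCENTILES:
            m = generate_percentile_model(female_model, "female", p)
            factors.append(m.metadata["cumulative_scale"]["C4"][0])
        assert all(b > a for a, b in zip(factors, factors[1:]))

    def test_percentile_mass_is_recalibrated(self, male_model):
        p95 = generate_percentile_model(male_model, "male", 95)
        total = sum(s.mass for s in p95.segments.values())
        assert total == pytest.approx(110.7, abs=1e-9)


class TestFemaleDerivation:
    def test_target_ratio_arithmetic(self):
        derived = tables.derive_female_targets()
        assert derived["extension"] == 165
        assert derived["axial_rotation"] == 7.3

    def test_topology_preserved(self, male_model, female_model):
        assert [f.name for f in female_model.fascicles] == [
            f.name for f in male_model.fascicles
        ]

    def test_total_volume_ratio(self, male_model):
        female = derive_female_model(male_model)
        male_total = sum(muscle_volume(f) for f in male_model.fascicles)
        female_total = sum(muscle_volume(f) for f in female.fascicles)
        assert female_total / male_total == pytest.approx(510.4 / 813.9, abs=1e-6)


class TestSymmetrize:
    def test_symmetric_model_unchanged(self, male_model):
        out = symmetrize(male_model)
        assert model_to_dict(out) == model_to_dict(male_model)

    def test_perturbed_side_averages_midway(self, male_model):
        bent = male_model.copy()
        f = bent.fascicle("stern_mast_R")
        f.f_max += 10.0
        out = symmetrize(bent)
        expected = male_model.fascicle("stern_mast_R").f_max + 5.0
        assert out.fascicle("stern_mast_R").f_max == pytest.approx(expected)
        assert out.fascicle("stern_mast_L").f_max == pytest.approx(expected)

    def test_idempotent(self, male_model):
        bent = male_model.copy()
        bent.fascicle("trap_acr_L").nodes[0].position += [0.001, 0.002, 0.0]
        once = symmetrize(bent)
        twice = symmetrize(once)
        assert model_to_dict(once) == model_to_dict(twice)
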