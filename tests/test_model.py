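"""Model structure, validation, kinematics and serialization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from anthroneck import (
    build_default_model,
    distribute_neck_angle,
    load_model,
    save_model,
)
from anthroneck.model import (
    ModelValidationError,
    RangeOfMotionError,
    SymmetryError,
    model_from_dict,
    model_to_dict,
    segment_transforms,
)


class TestDefaultModel:
    def test_structure(self, male_model):
        assert len(male_model.joints) == 8
        assert [j.name for j in male_model.joints] == [
            "C7-T1", "C6-C7", "C5-C6", "C4-C5", "C3-C4", "C2-C3", "C1-C2", "OC-C1",
        ]
        assert len(male_model.fascicles) == 88  # 44 base names, mirrored
        male_model.validate()

    @pytest.mark.parametrize(
        "gender,field,value",
        [
            ("male", "height_m", 1.76),
            ("male", "body_mass_kg", 84.6),
            ("male", "neck_circumference_cm", 39.5),
            ("male", "neck_length_cm", 10.8),
            ("female", "height_m", 1.63),
            ("female", "neck_circumference_cm", 32.8),
            ("female", "neck_length_cm", 10.6),
        ],
    )
    def test_reference_anthropometry(self, gender, field, value):
        m = build_default_model(gender)
        assert getattr(m.reference_anthropometry, field) == pytest.approx(value)

    def test_genders_share_fascicle_topology(self, male_model, female_model):
        male_names = [(f.name, len(f.nodes)) for f in male_model.fascicles]
        female_names = [(f.name, len(f.nodes)) for f in female_model.fascicles]
        assert male_names == female_names

    def test_unknown_gender_rejected(self):
        with pytest.raises(ValueError, match="gender"):
            build_default_model("other")


class TestValidation:
    def test_bad_contribution_fractions(self, male_model):
        broken = male_model.copy()
        broken.joints[0].contribution_fraction = np.array([0.025, 0.125, 0.125])
        with pytest.raises(ModelValidationError, match="sum to 1"):
            broken.validate()

    def test_negative_mass(self, male_model):
        broken = male_model.copy()
        broken.segments["skull"].mass = -1.0
        with pytest.raises(ModelValidationError, match="mass"):
            broken.validate()

    def test_non_orthonormal_axes(self, male_model):
        broken = male_model.copy()
        broken.segments["C4"].axes = np.eye(3) * 1.01
        with pytest.raises(ModelValidationError, match="orthonormal"):
            broken.validate()

    def test_indefinite_inertia(self, male_model):
        broken = male_model.copy()
        broken.segments["skull"].inertia = np.diag([1.0, 1.0, -0.1])
        with pytest.raises(ModelValidationError, match="semidefinite"):
            broken.validate()

    def test_unpaired_fascicle(self, male_model):
        broken = male_model.copy()
        broken.fascicles = [f for f in broken.fascicles if f.name != "stern_mast_R"]
        with pytest.raises(SymmetryError, match="stern_mast"):
            broken.validate()

    def test_unknown_attachment_segment(self, male_model):
        broken = male_model.copy()
        broken.fascicles[0].nodes[0].attached_segment = "L5"
        with pytest.raises(ModelValidationError, match="L5"):
            broken.validate()

    def test_force_landmark_must_be_on_skull(self, male_model):
        broken = male_model.copy()
        broken.landmarks["forehead"].attached_segment = "torso"
        with pytest.raises(ModelValidationError, match="forehead"):
            broken.validate()


class TestSerialization:
    def test_round_trip_lossless(self, male_model, tmp_path):
        path = tmp_path / "male.json"
        save_model(male_model, path)
        loaded = load_model(path)
        a, b = model_to_dict(male_model), model_to_dict(loaded)

        def assert_equal(x, y, where=""):
            if isinstance(x, dict):
                assert x.keys() == y.keys(), where
                for k in x:
                    assert_equal(x[k], y[k], f"{where}.{k}")
            elif isinstance(x, list):
                assert len(x) == len(y), where
                for i, (xi, yi) in enumerate(zip(x, y)):
                    assert_equal(xi, yi, f"{where}[{i}]")
            elif isinstance(x, float):
                assert abs(x - y) <= 1e-12, f"{where}: {x} != {y}"
            else:
                assert x == y, where

        assert_equal(a, b)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_model(tmp_path / "nope.json")

    def test_invalid_model_file_names_field(self, male_model):
        data = model_to_dict(male_model)
        del data["joints"][0]["center"]
        with pytest.raises(ModelValidationError, match="center"):
            model_from_dict(data)


class TestKinematics:
    def test_zero_angle_gives_zero_everywhere(self, male_model):
        angles = distribute_neck_angle(male_model, [0.0, 0.0, 0.0])
        assert np.all(angles == 0.0)

    def test_uniform_fractions_arithmetic(self, male_model):
        angles = distribute_neck_angle(male_model, [0.0, 0.4, 0.0])
        assert np.allclose(angles[:, 1], 0.05)
        assert np.allclose(angles[:, [0, 2]], 0.0)

    def test_out_of_range_rejected(self, male_model):
        with pytest.raises(RangeOfMotionError):
            distribute_neck_angle(male_model, [0.0, 3.0, 0.0])

    @settings(max_examples=25, deadline=None)
    @given(
        fracs=st.lists(st.floats(0.01, 1.0), min_size=8, max_size=8),
        a=st.floats(-0.5, 0.5),
        b=st.floats(-0.5, 0.5),
    )
    def test_distribution_sums_and_is_linear(self, male_model, fracs, a, b):
        model = male_model.copy()
        fr = np.array(fracs)
        fr = fr / fr.sum()
        for j, f in zip(model.joints, fr):
            j.contribution_fraction = np.array([f, f, f])
        ya = distribute_neck_angle(model, [a, 0, 0])
        yb = distribute_neck_angle(model, [b, 0, 0])
        yab = distribute_neck_angle(model, [a + b, 0, 0])
        assert np.allclose(ya.sum(axis=0), [a, 0, 0], atol=1e-12)
        assert np.allclose(ya + yb, yab, atol=1e-12)

    def test_neutral_transforms_are_identity(self, male_model):
        tf = segment_transforms(male_model, None)
        for r, t in tf.values():
            assert np.allclose(r, np.eye(3))
            assert np.allclose(t, 0.0)

    def test_rotation_moves_distal_segments_only(self, male_model):
        angles = np.zeros((8, 3))
        angles[4, 1] = 0.2  # C3-C4 flexion
        tf = segment_transforms(male_model, angles)
        assert np.allclose(tf["torso"][0], np.eye(3))
        assert np.allclose(tf["C5"][0], np.eye(3))  # below the rotated joint
        assert not np.allclose(tf["C3"][0], np.eye(3))
        assert not np.allclose(tf["skull"][0], np.eye(3))
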