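"""Parametric synthetic bodies and analytic test fixtures.

``make_body_mesh`` builds a watertight head/neck/torso surface as a
generalized cylinder (stacked elliptical cross-sections closed by polar
caps) with named landmarks, sized by the same four measurements the
scaling module uses. It is a stylized stand-in for statistical body-scan
surfaces: circumference/length/mass relationships are honoured, skin shape
realism is not attempted.

``make_toy_fixture`` returns small neck models whose strengths are known
in closed form, used as oracles across the test suites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from . import tables
from ._geometry import FEMALE_REFERENCE, MALE_REFERENCE
from .inertia import SegmentationRule, axis_plane_rules
from .model import (
    AnthropometryFeatures,
    Joint,
    Landmark,
    MuscleFascicle,
    MuscleNode,
    NeckModel,
    Segment,
    build_default_model,
)


@dataclass
class BodyParams:
    """Dimensions of the synthetic body surface."""

    gender: str = "male"
    height_m: float = MALE_REFERENCE.height_m
    body_mass_kg: float = MALE_REFERENCE.body_mass_kg
    neck_circumference_cm: float = MALE_REFERENCE.neck_circumference_cm
    neck_length_cm: float = MALE_REFERENCE.neck_length_cm
    head_breadth_m: float = 0.152
    head_length_m: float = 0.196
    head_height_m: float = 0.225
    ring_segments: int = 64
    sections_per_part: int = 24

    @classmethod
    def default(cls, gender: str = "male") -> "BodyParams":
        ref = {"male": MALE_REFERENCE, "female": FEMALE_REFERENCE}[
            tables._check_gender(gender)
        ]
        head = {"male": (0.152, 0.196, 0.225), "female": (0.144, 0.186, 0.212)}[gender]
        return cls(
            gender=gender,
            height_m=ref.height_m,
            body_mass_kg=ref.body_mass_kg,
            neck_circumference_cm=ref.neck_circumference_cm,
            neck_length_cm=ref.neck_length_cm,
            head_breadth_m=head[0],
            head_length_m=head[1],
            head_height_m=head[2],
        )

    def validate(self) -> None:
        for name in ("height_m", "body_mass_kg", "neck_circumference_cm",
                     "neck_length_cm", "head_breadth_m", "head_length_m",
                     "head_height_m"):
            if not getattr(self, name) > 0:
                raise ValueError(f"BodyParams.{name} must be > 0")
        if self.ring_segments < 8:
            raise ValueError("ring_segments too coarse for a watertight surface")


def _polygon_radius(circumference: float, n: int) -> float:
    """Circumradius whose n-gon perimeter equals the circumference."""
    return circumference / (2.0 * n * np.sin(np.pi / n))


def make_body_mesh(params: BodyParams | None = None):
    """Watertight torso+neck+head surface and its landmark positions.

    Returns ``(mesh, landmarks)`` with the neck base (C7 level) at z = 0.
    The planar-slice perimeter at Adam's-apple height matches the requested
    neck circumference to well under 1 %.
    """
    params = params or BodyParams.default()
    params.validate()
    n = params.ring_segments
    neck_len = params.neck_length_cm / 100.0
    r_neck = _polygon_radius(params.neck_circumference_cm / 100.0, n)
    torso_depth = 0.115  # semi-axis x
    torso_width = 0.17
    torso_bottom = -0.55
    head_a = params.head_length_m / 2.0
    head_b = params.head_breadth_m / 2.0
    head_h = params.head_height_m
    z_head_base = neck_len
    z_top = z_head_base + head_h

    # cross-section control points: (z, semi_x, semi_y, center_x)
    controls = np.array([
        (torso_bottom, torso_depth * 0.9, torso_width * 0.9, -0.02),
        (-0.30, torso_depth, torso_width, -0.02),
        (-0.10, torso_depth, torso_width, -0.015),
        (-0.03, r_neck * 1.6, r_neck * 2.2, 0.0),
        (0.0, r_neck, r_neck, 0.0),
        (z_head_base, r_neck, r_neck, 0.0),
        (z_head_base + 0.25 * head_h, head_a * 0.85, head_b * 0.85, 0.01),
        (z_head_base + 0.55 * head_h, head_a, head_b, 0.01),
        (z_head_base + 0.85 * head_h, head_a * 0.72, head_b * 0.72, 0.005),
        (z_top, head_a * 0.18, head_b * 0.18, 0.0),
    ])
    n_sections = 4 * params.sections_per_part
    zs = np.linspace(torso_bottom, z_top, n_sections)
    ax = np.interp(zs, controls[:, 0], controls[:, 1])
    by = np.interp(zs, controls[:, 0], controls[:, 2])
    cx = np.interp(zs, controls[:, 0], controls[:, 3])
    # keep the neck prismatic so the slice perimeter is exact
    neck_band = (zs >= 0.0) & (zs <= z_head_base)
    ax[neck_band] = r_neck
    by[neck_band] = r_neck
    cx[neck_band] = 0.0

    theta = 2.0 * np.pi * np.arange(n) / n
    ct, st = np.cos(theta), np.sin(theta)
    verts = []
    for z, a, b, c in zip(zs, ax, by, cx):
        ring = np.column_stack([c + a * ct, b * st, np.full(n, z)])
        verts.append(ring)
    verts = np.vstack(verts)
    bottom_center = np.array([[controls[0, 3], 0.0, torso_bottom]])
    top_center = np.array([[0.0, 0.0, z_top]])
    verts = np.vstack([verts, bottom_center, top_center])
    i_bottom, i_top = len(verts) - 2, len(verts) - 1

    faces = []
    for k in range(n_sections - 1):
        base0, base1 = k * n, (k + 1) * n
        for i in range(n):
            j = (i + 1) % n
            faces.append([base0 + i, base0 + j, base1 + i])
            faces.append([base0 + j, base1 + j, base1 + i])
    for i in range(n):  # caps
        j = (i + 1) % n
        faces.append([i, i_bottom, j])
        faces.append([(n_sections - 1) * n + i, (n_sections - 1) * n + j, i_top])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)
    if not mesh.is_watertight:  # pragma: no cover - construction guarantees it
        raise ValueError("generated mesh is not watertight; increase resolution")

    landmarks = {
        "C7": np.array([-r_neck, 0.0, 0.0]),
        "clavicle": np.array([0.02, 0.10, -0.04]),
        "adams_apple": np.array([r_neck, 0.0, 0.45 * neck_len]),
        "tragion_left": np.array([0.0, head_b - 0.005, z_head_base + 0.02]),
        "tragion_right": np.array([0.0, -(head_b - 0.005), z_head_base + 0.02]),
        "forehead": np.array([head_a, 0.0, z_head_base + 0.62 * head_h]),
        "opisthocranion": np.array([-head_a + 0.01, 0.0, z_head_base + 0.55 * head_h]),
        "temple": np.array([0.02, head_b - 0.003, z_head_base + 0.68 * head_h]),
    }
    return mesh, landmarks


def slice_perimeter(mesh: trimesh.Trimesh, z: float) -> float:
    """Perimeter of the planar cross-section at height z."""
    section = mesh.section(plane_origin=[0, 0, z], plane_normal=[0, 0, 1])
    if section is None:
        return 0.0
    planar, _ = section.to_2D()
    return float(sum(planar.polygons_closed[i].length
                     for i in range(len(planar.polygons_closed))
                     if planar.polygons_closed[i] is not None))


def default_segmentation_rules(landmarks: dict[str, np.ndarray]) -> list[SegmentationRule]:
    """Head / neck / torso separation planes from named landmarks.

    The head-neck plane passes through the midpoint of the two tragion
    landmarks; the neck-torso plane through the C7/clavicle-weighted lower
    neck point; both with z normals.
    """
    z_head = 0.5 * (landmarks["tragion_left"][2] + landmarks["tragion_right"][2])
    z_torso = 0.7 * landmarks["C7"][2] + 0.3 * landmarks["clavicle"][2]
    return axis_plane_rules([("torso", z_torso), ("neck", z_head), ("head", np.inf)])


# ---------------------------------------------------------------------------
# Analytic toy fixtures
# ---------------------------------------------------------------------------

@dataclass
class ToyFixture:
    name: str
    model: NeckModel
    analytic: dict = field(default_factory=dict)


def _hinge_model(fascicle_specs: list[tuple[str, str, float, float, float]]) -> NeckModel:
    """A torso-skull model with one hinge joint at the origin.

    ``fascicle_specs`` rows are (name, side, f_max, x_offset, y_offset) of a
    vertical 2-node muscle from torso (z=-0.05) to skull (z=+0.05).
    """
    segments = {
        "torso": Segment(name="torso", parent_joint=None, origin=np.zeros(3),
                         mass=1.0, com=np.array([0.0, 0.0, -0.05]),
                         inertia=np.eye(3) * 1e-3),
        "skull": Segment(name="skull", parent_joint="OC-C1", origin=np.zeros(3),
                         mass=1.0, com=np.zeros(3), inertia=np.eye(3) * 1e-3),
    }
    joints = [Joint(name="OC-C1", center=np.zeros(3), parent_segment="torso",
                    child_segment="skull", contribution_fraction=np.ones(3))]
    fascicles = []
    for name, side, fmax, x, y in fascicle_specs:
        fascicles.append(MuscleFascicle(
            name=name, group="longus_capitis", side=side,
            nodes=[MuscleNode("torso", np.array([x, y, -0.05])),
                   MuscleNode("skull", np.array([x, y, 0.05]))],
            f_max=fmax, optimal_fiber_length=0.05, tendon_slack_length=0.05,
        ))
    landmarks = {
        "forehead": Landmark("forehead", np.array([0.05, 0.0, 0.15]), "skull"),
        "opisthocranion": Landmark("opisthocranion", np.array([-0.05, 0.0, 0.15]), "skull"),
        "temple": Landmark("temple", np.array([0.0, 0.05, 0.15]), "skull"),
    }
    model = NeckModel(
        gender="male", segments=segments, joints=joints, fascicles=fascicles,
        landmarks=landmarks,
        reference_anthropometry=MALE_REFERENCE,
        metadata={"fixture": True},
    )
    model.validate()
    return model


def make_toy_fixture(name: str) -> ToyFixture:
    """Small models with closed-form expectations.

    * ``single_hinge`` — one vertical flexor (f_max 100 N) at moment arm
      r = 0.03 m, load lever d = 0.15 m: flexion strength f r / d = 20 N.
    * ``twin_muscle`` — two mirrored copies of the same muscle: equal force
      sharing, flexion strength 40 N.
    * ``full_default`` — the packaged male model with the published
      original maximum isometric forces attached for cross-checks.
    """
    if name == "single_hinge":
        f_max, r, d = 100.0, 0.03, 0.15
        model = _hinge_model([("hinge_flexor", "midline", f_max, r, 0.0)])
        return ToyFixture(name=name, model=model, analytic={
            "mode": "flexion", "f_max": f_max, "moment_arm": r, "lever": d,
            "strength": f_max * r / d,
            # tight feasibility threshold: the analytic value assumes exact
            # capacity, so the failure criterion must not add visible margin
            "residual_tolerance": 0.01,
        })
    if name == "twin_muscle":
        f_max, r, d = 100.0, 0.03, 0.15
        model = _hinge_model([
            ("twin_flexor_L", "left", f_max, r, 0.02),
            ("twin_flexor_R", "right", f_max, r, -0.02),
        ])
        return ToyFixture(name=name, model=model, analytic={
            "mode": "flexion", "strength": 2.0 * f_max * r / d,
            "equal_sharing": True, "moment_arm": r, "lever": d, "f_max": f_max,
            "residual_tolerance": 0.01,
        })
    if name == "full_default":
        model = build_default_model("male")
        return ToyFixture(name=name, model=model,
                          analytic={"original_f_max": tables.original_fmax()})
    raise ValueError(f"unknown fixture {name!r}; expected single_hinge, "
                     "twin_muscle or full_default")
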