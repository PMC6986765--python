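"""Synthetic default geometry for the 50th-percentile male neck model.

The published source of the original muscle-path coordinates is not
available, so the default model uses a documented synthetic geometry:

* the eight cervical joint centres are stacked on the z axis at uniform
  spacing summing to the reference neck length (C7-T1 at the origin,
  OC-C1 at neck-length height);
* fascicle attachment nodes sit at anatomically motivated anterior/
  posterior/lateral offsets, on or inside a cylinder of the reference neck
  radius (circumference / 2*pi), with skull and shoulder attachments on
  plausible skull/torso points;
* fascicle names and maximum isometric forces are the published
  original-model values; the two added deep flexors (rectus capitis
  anterior and lateralis) start at 32.5 N;
* per muscle group, one optimal fiber length is chosen so the model's
  group volume fractions equal the published male distribution exactly
  (total volume 813.9 cm^3 at 35 N/cm^2 specific tension).

The attachment offsets below were designed, and numerically refined against
the model's own strength evaluation, so that the volume-constrained model
reproduces realistic ratios between extension, flexion, lateral-bending and
axial-rotation strength; see docs/methods.md.
"""

from __future__ import annotations

import numpy as np

from . import tables
from .model import (
    AnthropometryFeatures,
    Joint,
    Landmark,
    MuscleFascicle,
    MuscleNode,
    NeckModel,
    Segment,
    JOINT_NAMES,
)

MALE_REFERENCE = AnthropometryFeatures(
    height_m=1.76, body_mass_kg=84.6, neck_circumference_cm=39.5, neck_length_cm=10.8
)
FEMALE_REFERENCE = AnthropometryFeatures(
    height_m=1.63, body_mass_kg=66.8, neck_circumference_cm=32.8, neck_length_cm=10.6
)

SPECIFIC_TENSION = 35.0  # N/cm^2, lower bound of the literature span
RECTCAP_INITIAL_FMAX = 32.5  # N, published initial strength of the added flexors
RECTCAP_FIBER_LENGTH = 0.025  # m, plausible fiber length for the short deep flexors

NECK_LENGTH = MALE_REFERENCE.neck_length_cm / 100.0  # 0.108 m
_H = NECK_LENGTH / 7.0  # joint spacing

HEAD_MASS = 4.20  # kg
NECK_MASS = 1.66  # kg, whole cervical column, split equally over C1..C7

# world z of the 8 joint centres, C7-T1 (index 0) .. OC-C1 (index 7)
JOINT_Z = [i * _H for i in range(8)]

# (name, group, f_max N, nodes [(segment, x, y, z_world)]) — left side, y >= 0.
# x anterior, y left-lateral, z superior; coordinates in metres.
MUSCLE_TABLE = [
    # --- sternocleidomastoid: sternum/clavicle -> mastoid/occiput ---------
    ("stern_mast", "sternocleidomastoid", 86.1,
     [("torso", 0.082, 0.012, -0.050), ("C6", 0.058, 0.048, 0.025), ("skull", -0.008, 0.066, 0.105)]),
    ("cleid_mast", "sternocleidomastoid", 43.1,
     [("torso", 0.062, 0.040, -0.040), ("C6", 0.048, 0.050, 0.025), ("skull", -0.008, 0.066, 0.105)]),
    ("cleid_occ", "sternocleidomastoid", 43.1,
     [("torso", 0.062, 0.044, -0.040), ("C6", 0.038, 0.056, 0.025), ("skull", -0.022, 0.055, 0.112)]),
    # --- scalenes: first/second rib -> mid-cervical transverse processes --
    ("scalenus_ant", "scalenus", 65.8,
     [("torso", 0.022, 0.026, -0.050), ("C4", 0.008, 0.030, 0.054)]),
    ("scalenus_med", "scalenus", 65.8,
     [("torso", 0.008, 0.028, -0.050), ("C4", 0.000, 0.032, 0.054)]),
    ("scalenus_post", "scalenus", 36.8,
     [("torso", 0.000, 0.030, -0.055), ("C5", 0.000, 0.032, 0.039)]),
    # --- deep flexors -----------------------------------------------------
    ("long_cap_sklc4", "longus_capitis", 48.0,
     [("C4", 0.020, 0.012, 0.050), ("skull", 0.016, 0.012, 0.114)]),
    ("long_col_c1thx", "longus_colli", 14.4,
     [("torso", 0.020, 0.008, -0.020), ("C1", 0.017, 0.008, 0.100)]),
    ("long_col_c1c5", "longus_colli", 14.4,
     [("C5", 0.020, 0.010, 0.039), ("C1", 0.017, 0.008, 0.100)]),
    ("long_col_c5thx", "longus_colli", 14.4,
     [("torso", 0.020, 0.008, -0.020), ("C5", 0.020, 0.010, 0.039)]),
    # --- trapezius: occiput -> clavicle/acromion --------------------------
    ("trap_cl", "trapezius", 132.0,
     [("skull", -0.010, 0.030, 0.112), ("torso", -0.003, 0.040, -0.030)]),
    ("trap_acr", "trapezius", 348.6,
     [("skull", -0.009, 0.020, 0.112), ("torso", -0.038, 0.042, -0.050)]),
    # --- splenius ---------------------------------------------------------
    ("splen_cap_sklc6", "splenius", 55.0,
     [("skull", -0.008, 0.072, 0.106), ("C6", -0.023, 0.012, 0.023)]),
    ("splen_cap_sklthx", "splenius", 53.2,
     [("skull", -0.010, 0.070, 0.106), ("C4", -0.032, 0.068, 0.050), ("torso", -0.027, 0.002, -0.045)]),
    ("splen_cerv_c3thx", "splenius", 50.1,
     [("C3", -0.013, 0.040, 0.069), ("torso", -0.023, 0.014, -0.050)]),
    # --- semispinalis capitis --------------------------------------------
    ("semi_cap_sklc5", "semispinalis_capitis", 91.7,
     [("skull", -0.008, 0.022, 0.112), ("C5", -0.023, 0.018, 0.039)]),
    ("semi_cap_sklthx", "semispinalis_capitis", 101.5,
     [("skull", -0.008, 0.018, 0.112), ("C4", -0.028, 0.058, 0.050), ("torso", -0.020, 0.002, -0.050)]),
    # --- semispinalis cervicis and multifidus ----------------------------
    ("semi_cerv_c3thx", "semispinalis_cervicis_multifidus", 107.1,
     [("C3", -0.020, 0.012, 0.069), ("C6", -0.026, 0.050, 0.025), ("torso", -0.020, 0.002, -0.050)]),
    ("supmult-C4/5-C2", "semispinalis_cervicis_multifidus", 14.7,
     [("C5", -0.024, 0.035, 0.042), ("C2", -0.031, 0.008, 0.085)]),
    ("supmult-C5/6-C2", "semispinalis_cervicis_multifidus", 19.3,
     [("C6", -0.024, 0.035, 0.027), ("C2", -0.031, 0.008, 0.085)]),
    ("supmult-C6/7-C2", "semispinalis_cervicis_multifidus", 15.8,
     [("C7", -0.024, 0.035, 0.011), ("C2", -0.031, 0.008, 0.085)]),
    ("supmult-T1-C4", "semispinalis_cervicis_multifidus", 16.3,
     [("torso", -0.024, 0.035, -0.020), ("C4", -0.029, 0.008, 0.054)]),
    ("supmult-T1-C5", "semispinalis_cervicis_multifidus", 11.7,
     [("torso", -0.024, 0.035, -0.020), ("C5", -0.029, 0.008, 0.039)]),
    ("supmult-T2-C6", "semispinalis_cervicis_multifidus", 6.5,
     [("torso", -0.024, 0.035, -0.045), ("C6", -0.029, 0.008, 0.023)]),
    ("deepmult-C4/5-C2", "semispinalis_cervicis_multifidus", 7.4,
     [("C5", -0.021, 0.026, 0.042), ("C2", -0.027, 0.006, 0.083)]),
    ("deepmult-C5/6-C3", "semispinalis_cervicis_multifidus", 12.3,
     [("C6", -0.021, 0.026, 0.027), ("C3", -0.027, 0.006, 0.068)]),
    ("deepmult-C6/7-C4", "semispinalis_cervicis_multifidus", 16.1,
     [("C7", -0.021, 0.026, 0.011), ("C4", -0.027, 0.006, 0.052)]),
    ("deepmult-T1-C5", "semispinalis_cervicis_multifidus", 12.3,
     [("torso", -0.021, 0.026, -0.018), ("C5", -0.027, 0.006, 0.037)]),
    ("deepmult-T1-C6", "semispinalis_cervicis_multifidus", 8.3,
     [("torso", -0.021, 0.026, -0.018), ("C6", -0.027, 0.006, 0.022)]),
    ("deepmult-T2-C7", "semispinalis_cervicis_multifidus", 14.0,
     [("torso", -0.021, 0.034, -0.042), ("C7", -0.029, 0.004, 0.007)]),
    ("deepmult-T2-T1", "semispinalis_cervicis_multifidus", 14.0,
     [("torso", -0.021, 0.034, -0.042), ("torso", -0.029, 0.004, -0.002)]),
    # --- longissimus / iliocostalis --------------------------------------
    ("longissi_cap_sklc6", "longissimus_capitis", 34.3,
     [("skull", 0.000, 0.050, 0.104), ("C6", -0.012, 0.028, 0.023)]),
    ("longissi_cerv_c4thx", "longissimus_cervicis", 52.2,
     [("C4", -0.015, 0.028, 0.054), ("torso", -0.020, 0.028, -0.050)]),
    ("iliocost_cerv_c5rib", "longissimus_cervicis", 36.4,
     [("C5", -0.012, 0.030, 0.039), ("torso", -0.015, 0.036, -0.060)]),
    # --- levator scapulae -------------------------------------------------
    ("levator_scap", "levator_scapulae", 109.2,
     [("C1", 0.000, 0.040, 0.100), ("torso", -0.058, 0.054, -0.060)]),
    # --- suboccipitals ----------------------------------------------------
    ("rectcap_post_maj", "rectus_capitis_major", 58.8,
     [("skull", -0.040, 0.020, 0.112), ("C2", -0.045, 0.010, 0.085)]),
    ("rectcap_post_min", "rectus_capitis_minor", 32.2,
     [("skull", -0.034, 0.012, 0.112), ("C1", -0.038, 0.008, 0.099)]),
    ("obl_cap_sup", "obliquus_capitis_superior", 30.8,
     [("C1", 0.000, 0.050, 0.100), ("skull", -0.024, 0.042, 0.114)]),
    ("obl_cap_inf", "obliquus_capitis_inferior", 68.3,
     [("C2", -0.045, 0.010, 0.083), ("C1", 0.005, 0.052, 0.100)]),
    # --- infrahyoids, routed via the clenched jaw to the skull ------------
    ("omohyoid", "infrahyoid", 26.3,
     [("torso", 0.000, 0.042, -0.045), ("skull", 0.038, 0.020, 0.115)]),
    ("sternohyoid", "infrahyoid", 20.3,
     [("torso", 0.040, 0.008, -0.045), ("skull", 0.040, 0.010, 0.115)]),
    ("sternothyroid", "infrahyoid", 22.8,
     [("torso", 0.040, 0.014, -0.050), ("skull", 0.040, 0.014, 0.115)]),
    # --- added deep flexors (rectus capitis anterior / lateralis) ---------
    ("rectcap_ant", tables.RECTCAP_GROUP, RECTCAP_INITIAL_FMAX,
     [("C1", 0.022, 0.014, 0.100), ("skull", 0.026, 0.014, 0.113)]),
    ("rectcap_lat", tables.RECTCAP_GROUP, RECTCAP_INITIAL_FMAX,
     [("C1", 0.006, 0.045, 0.100), ("skull", 0.010, 0.048, 0.113)]),
]

# world landmark positions (attached segment, x, y, z)
LANDMARK_TABLE = {
    "forehead": ("skull", 0.095, 0.000, 0.196),
    "opisthocranion": ("skull", -0.095, 0.000, 0.184),
    "temple": ("skull", 0.020, 0.075, 0.212),
    "tragion_left": ("skull", 0.005, 0.070, 0.108),
    "tragion_right": ("skull", 0.005, -0.070, 0.108),
    "C7": ("torso", -0.065, 0.000, 0.000),
    "clavicle": ("torso", 0.020, 0.070, -0.020),
    "adams_apple": ("C5", 0.0629, 0.000, 0.045),
}


def _segments() -> dict[str, Segment]:
    segs: dict[str, Segment] = {}
    segs["torso"] = Segment(
        name="torso", parent_joint=None, origin=np.zeros(3),
        mass=MALE_REFERENCE.body_mass_kg - HEAD_MASS - NECK_MASS,
        com=np.array([-0.02, 0.0, -0.35]),
        inertia=np.diag([1.5, 1.4, 0.35]),
    )
    cerv_names = ["C7", "C6", "C5", "C4", "C3", "C2", "C1"]
    for i, name in enumerate(cerv_names):
        z0 = JOINT_Z[i]
        segs[name] = Segment(
            name=name, parent_joint=JOINT_NAMES[i], origin=np.array([0.0, 0.0, z0]),
            mass=NECK_MASS / 7.0,
            com=np.array([0.0, 0.0, _H / 2.0]),
            inertia=np.diag([6e-4, 6e-4, 5.5e-4]),
        )
    segs["skull"] = Segment(
        name="skull", parent_joint="OC-C1", origin=np.array([0.0, 0.0, JOINT_Z[7]]),
        mass=HEAD_MASS,
        com=np.array([0.02, 0.0, 0.057]),
        inertia=np.diag([0.0200, 0.0230, 0.0170]),
    )
    return segs


def _joints() -> list[Joint]:
    chain = ["torso", "C7", "C6", "C5", "C4", "C3", "C2", "C1", "skull"]
    joints = []
    for i, name in enumerate(JOINT_NAMES):
        joints.append(
            Joint(
                name=name,
                center=np.array([0.0, 0.0, JOINT_Z[i]]),
                parent_segment=chain[i],
                child_segment=chain[i + 1],
                contribution_fraction=np.full(3, 1.0 / 8.0),
            )
        )
    return joints


def _group_fiber_lengths() -> dict[str, float]:
    """One optimal fiber length per group, matching the published male
    volume distribution exactly at the reference specific tension."""
    targets = tables.volume_fraction_targets("male")
    total = sum(targets.values())
    v_tot = tables.total_muscle_volume("male")
    fmax_by_group: dict[str, float] = {}
    for name, group, fmax, _nodes in MUSCLE_TABLE:
        if group in targets:
            fmax_by_group[group] = fmax_by_group.get(group, 0.0) + 2.0 * fmax
    out = {}
    for group, fsum in fmax_by_group.items():
        frac = targets[group] / total
        # volume [cm^3] = PCSA [cm^2] * fiber length [cm]
        out[group] = (frac * v_tot) / (fsum / SPECIFIC_TENSION) / 100.0  # m
    out[tables.RECTCAP_GROUP] = RECTCAP_FIBER_LENGTH
    return out


def _fascicles(segs: dict[str, Segment]) -> list[MuscleFascicle]:
    lopt = _group_fiber_lengths()
    fascicles = []
    for name, group, fmax, nodes in MUSCLE_TABLE:
        for side, sign in (("left", 1.0), ("right", -1.0)):
            mn = [
                MuscleNode(
                    attached_segment=seg,
                    position=np.array([x, sign * y, z]) - segs[seg].origin,
                )
                for seg, x, y, z in nodes
            ]
            pts = np.array([segs[n.attached_segment].origin + n.position for n in mn])
            path = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
            fl = lopt[group]
            fascicles.append(
                MuscleFascicle(
                    name=f"{name}_{'L' if side == 'left' else 'R'}",
                    group=group,
                    side=side,
                    nodes=mn,
                    f_max=fmax,
                    optimal_fiber_length=fl,
                    tendon_slack_length=max(path - fl, 0.0),
                )
            )
    return fascicles


def build_male_model(config: dict | None = None) -> NeckModel:
    config = config or {}
    segs = _segments()
    landmarks = {
        name: Landmark(name=name, position=np.array([x, y, z]) - segs[seg].origin,
                       attached_segment=seg)
        for name, (seg, x, y, z) in LANDMARK_TABLE.items()
    }
    model = NeckModel(
        gender="male",
        segments=segs,
        joints=_joints(),
        fascicles=_fascicles(segs),
        landmarks=landmarks,
        reference_anthropometry=MALE_REFERENCE,
        metadata={"source": "anthroneck synthetic default geometry", "version": 1},
    )
    fractions = config.get("contribution_fractions")
    if fractions is not None:
        fr = np.asarray(fractions, dtype=float)
        for j, row in zip(model.joints, fr):
            j.contribution_fraction = np.asarray(row, dtype=float)
    model.validate()
    return model
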