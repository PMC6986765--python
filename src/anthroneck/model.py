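"""Neck musculoskeletal model: data structures, validation, kinematics, JSON IO.

The model is a tree of rigid segments (torso root, C7..C1, skull) connected
by eight cervical joints (C7-T1 up to OC-C1). Each joint has three rotational
degrees of freedom about the global axes at neutral posture:

* x — anterior axis (lateral bending),
* y — left-lateral axis (flexion/extension),
* z — superior axis (axial rotation).

Intervertebral kinematics are prescribed: each joint realises a fixed
fraction of the overall head-to-T1 angle per direction, constant over the
range of motion. All positions are stored in metres in the attached
segment's local frame; at neutral posture every local frame is aligned with
the global frame, so world position = segment origin + local position.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import tables

GRAVITY = 9.80665  # m/s^2

JOINT_NAMES = ("C7-T1", "C6-C7", "C5-C6", "C4-C5", "C3-C4", "C2-C3", "C1-C2", "OC-C1")

#: per-direction range of motion (rad) for the overall neck angle
DEFAULT_RANGE_OF_MOTION = (math.radians(60.0), math.radians(90.0), math.radians(90.0))

FORCE_LANDMARKS = ("forehead", "opisthocranion", "temple")


class ModelValidationError(ValueError):
    """A model violates one of its structural invariants."""


class SymmetryError(ModelValidationError):
    """Left/right fascicle pairing is broken."""


class RangeOfMotionError(ValueError):
    """Requested overall neck angle outside the configured range of motion."""


def _vec3(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.shape != (3,):
        raise ModelValidationError(f"expected 3-vector, got shape {a.shape}")
    return a


def _mat3(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.shape != (3, 3):
        raise ModelValidationError(f"expected 3x3 matrix, got shape {a.shape}")
    return a


@dataclass
class AnthropometryFeatures:
    """Whole-body and neck measurements used for scaling.

    neck_circumference is measured at Adam's-apple height; neck_length is the
    vertical C7-to-tragion distance. Units: m, kg, cm, cm.
    """

    height_m: float
    body_mass_kg: float
    neck_circumference_cm: float
    neck_length_cm: float

    def validate(self) -> None:
        for name, v in asdict(self).items():
            if not v > 0:
                raise ModelValidationError(f"AnthropometryFeatures.{name} must be > 0, got {v}")


@dataclass
class Segment:
    """A rigid body segment with inertial properties about its COM.

    ``origin`` is the segment frame origin at neutral posture (world m);
    ``com`` and node/landmark positions are local to that origin. ``axes``
    rows are the segment's x/y/z axes (identity at neutral).
    """

    name: str
    parent_joint: str | None
    origin: np.ndarray
    mass: float
    com: np.ndarray
    inertia: np.ndarray
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.origin = _vec3(self.origin)
        self.com = _vec3(self.com)
        self.inertia = _mat3(self.inertia)
        self.axes = _mat3(self.axes)

    def validate(self) -> None:
        if not self.mass > 0:
            raise ModelValidationError(f"segment {self.name}: mass must be > 0, got {self.mass}")
        if not np.allclose(self.inertia, self.inertia.T, atol=1e-12):
            raise ModelValidationError(f"segment {self.name}: inertia tensor not symmetric")
        eig = np.linalg.eigvalsh(0.5 * (self.inertia + self.inertia.T))
        if eig.min() < -1e-12:
            raise ModelValidationError(
                f"segment {self.name}: inertia tensor not positive semidefinite ({eig.min():g})"
            )
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-9):
            raise ModelValidationError(f"segment {self.name}: axes not orthonormal within 1e-9")


@dataclass
class Joint:
    """A cervical joint with up to three rotational DOF.

    ``contribution_fraction`` holds, per overall-angle direction (x, y, z),
    the fixed share of the overall neck angle realised at this joint.
    ``center`` is the joint center at neutral (world m), attached to the
    parent (inferior) segment.
    """

    name: str
    center: np.ndarray
    parent_segment: str
    child_segment: str
    contribution_fraction: np.ndarray
    dof_axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.center = _vec3(self.center)
        self.contribution_fraction = _vec3(self.contribution_fraction)
        self.dof_axes = _mat3(self.dof_axes)

    def validate(self) -> None:
        if np.any(self.contribution_fraction < 0):
            raise ModelValidationError(f"joint {self.name}: negative contribution fraction")
        if not np.allclose(self.dof_axes @ self.dof_axes.T, np.eye(3), atol=1e-9):
            raise ModelValidationError(f"joint {self.name}: dof axes not orthonormal")


@dataclass
class Landmark:
    name: str
    position: np.ndarray  # local to attached segment
    attached_segment: str

    def __post_init__(self):
        self.position = _vec3(self.position)


@dataclass
class MuscleNode:
    """One point of a fascicle's polyline path (local to its segment)."""

    attached_segment: str
    position: np.ndarray

    def __post_init__(self):
        self.position = _vec3(self.position)


@dataclass
class MuscleFascicle:
    """A straight-line-segment muscle path with Hill parameters.

    ``f_max`` is the maximum isometric force (N); fiber and tendon lengths
    are metres. ``side`` is 'left', 'right' or 'midline'; paired fascicles
    share a ``base_name``.
    """

    name: str
    group: str
    side: str
    nodes: list[MuscleNode]
    f_max: float
    optimal_fiber_length: float
    tendon_slack_length: float

    @property
    def base_name(self) -> str:
        if self.side in ("left", "right"):
            return self.name.rsplit("_", 1)[0]
        return self.name

    def validate(self) -> None:
        if len(self.nodes) < 2:
            raise ModelValidationError(f"fascicle {self.name}: needs >= 2 nodes")
        if not self.f_max > 0:
            raise ModelValidationError(f"fascicle {self.name}: f_max must be > 0")
        if self.group not in tables.ALL_GROUPS:
            raise ModelValidationError(
                f"fascicle {self.name}: unknown muscle group {self.group!r}"
            )
        if self.side not in ("left", "right", "midline"):
            raise ModelValidationError(f"fascicle {self.name}: bad side {self.side!r}")


@dataclass
class NeckModel:
    """The complete scalable neck model."""

    gender: str
    segments: dict[str, Segment]
    joints: list[Joint]
    fascicles: list[MuscleFascicle]
    landmarks: dict[str, Landmark]
    reference_anthropometry: AnthropometryFeatures
    range_of_motion: tuple[float, float, float] = DEFAULT_RANGE_OF_MOTION
    metadata: dict = field(default_factory=dict)

    # -- structure helpers -------------------------------------------------
    def joint(self, name: str) -> Joint:
        for j in self.joints:
            if j.name == name:
                return j
        raise KeyError(name)

    def fascicle(self, name: str) -> MuscleFascicle:
        for f in self.fascicles:
            if f.name == name:
                return f
        raise KeyError(name)

    @property
    def joint_index(self) -> dict[str, int]:
        return {j.name: i for i, j in enumerate(self.joints)}

    def children_of(self, segment: str) -> list[str]:
        return [j.child_segment for j in self.joints if j.parent_segment == segment]

    def distal_segments(self, joint: Joint) -> list[str]:
        """Segments on the head side of ``joint`` (its child and descendants)."""
        out, stack = [], [joint.child_segment]
        while stack:
            s = stack.pop()
            out.append(s)
            stack.extend(self.children_of(s))
        return out

    def root_segments(self) -> list[str]:
        return [s.name for s in self.segments.values() if s.parent_joint is None]

    def world_landmark(self, name: str) -> np.ndarray:
        lm = self.landmarks[name]
        return self.segments[lm.attached_segment].origin + lm.position

    def world_nodes(self, fascicle: MuscleFascicle) -> np.ndarray:
        """Neutral-posture world positions of a fascicle's nodes, shape (n, 3)."""
        return np.array(
            [self.segments[n.attached_segment].origin + n.position for n in fascicle.nodes]
        )

    def f_max_vector(self) -> np.ndarray:
        return np.array([f.f_max for f in self.fascicles])

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if self.gender not in ("male", "female"):
            raise ModelValidationError(f"unknown gender {self.gender!r}")
        for seg in self.segments.values():
            seg.validate()
            if seg.parent_joint is not None and seg.parent_joint not in {
                j.name for j in self.joints
            }:
                raise ModelValidationError(
                    f"segment {seg.name}: unknown parent joint {seg.parent_joint}"
                )
        joint_names = set()
        for j in self.joints:
            j.validate()
            joint_names.add(j.name)
            for s in (j.parent_segment, j.child_segment):
                if s not in self.segments:
                    raise ModelValidationError(f"joint {j.name}: unknown segment {s}")
            if self.segments[j.child_segment].parent_joint != j.name:
                raise ModelValidationError(
                    f"joint {j.name}: child segment {j.child_segment} does not list it "
                    "as parent_joint"
                )
        # contribution fractions sum to 1 per direction
        fracs = np.array([j.contribution_fraction for j in self.joints])
        sums = fracs.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ModelValidationError(
                f"contribution fractions must sum to 1 per direction, got {sums}"
            )
        # connected tree rooted at a root segment
        roots = self.root_segments()
        if not roots:
            raise ModelValidationError("model has no root segment")
        reachable = set(roots)
        frontier = list(roots)
        while frontier:
            s = frontier.pop()
            for c in self.children_of(s):
                if c in reachable:
                    raise ModelValidationError(f"segment {c} reached twice; not a tree")
                reachable.add(c)
                frontier.append(c)
        if reachable != set(self.segments):
            raise ModelValidationError(
                f"segments not connected to root: {set(self.segments) - reachable}"
            )
        # fascicles
        names = set()
        for f in self.fascicles:
            f.validate()
            if f.name in names:
                raise ModelValidationError(f"duplicate fascicle name {f.name}")
            names.add(f.name)
            for n in f.nodes:
                if n.attached_segment not in self.segments:
                    raise ModelValidationError(
                        f"fascicle {f.name}: unknown segment {n.attached_segment}"
                    )
        self.paired_fascicles()  # raises SymmetryError on broken pairs
        # landmarks
        for lm in self.landmarks.values():
            if lm.attached_segment not in self.segments:
                raise ModelValidationError(
                    f"landmark {lm.name}: unknown segment {lm.attached_segment}"
                )
        skull = self.skull_segment()
        for name in FORCE_LANDMARKS:
            if name in self.landmarks and self.landmarks[name].attached_segment != skull:
                raise ModelValidationError(
                    f"force-application landmark {name} must attach to the skull segment"
                )
        self.reference_anthropometry.validate()

    def paired_fascicles(self) -> list[tuple[MuscleFascicle, MuscleFascicle]]:
        """Left/right fascicle pairs; raises SymmetryError on unpaired sides."""
        by_base: dict[str, dict[str, MuscleFascicle]] = {}
        for f in self.fascicles:
            if f.side in ("left", "right"):
                by_base.setdefault(f.base_name, {})[f.side] = f
        pairs = []
        for base, sides in by_base.items():
            if set(sides) != {"left", "right"}:
                raise SymmetryError(f"fascicle {base!r} present only on {sorted(sides)} side")
            pairs.append((sides["left"], sides["right"]))
        return pairs

    def skull_segment(self) -> str:
        # the segment with no children (tip of the chain through the joints)
        parents = {j.parent_segment for j in self.joints}
        tips = [j.child_segment for j in self.joints if j.child_segment not in parents]
        return tips[0] if tips else next(iter(self.segments))

    def copy(self) -> "NeckModel":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    c, s = math.cos(angle), math.sin(angle)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) * c + s * k + (1 - c) * np.outer(axis, axis)


def joint_rotation(joint: Joint, angles: np.ndarray) -> np.ndarray:
    """Rotation matrix for one joint, composing its x, y then z DOF."""
    r = np.eye(3)
    for d in range(3):
        if angles[d] != 0.0:
            r = r @ _axis_rotation(joint.dof_axes[d], angles[d])
    return r


def distribute_neck_angle(model: NeckModel, overall_angle) -> np.ndarray:
    """Distribute an overall neck angle over the joints.

    ``overall_angle`` is a 3-vector (rad) of lateral-bending / flexion /
    axial-rotation angles of the head relative to T1. Returns an
    (n_joints, 3) array where row j is ``contribution_fraction * overall``.
    """
    overall = _vec3(overall_angle)
    rom = np.asarray(model.range_of_motion)
    if np.any(np.abs(overall) > rom + 1e-12):
        raise RangeOfMotionError(
            f"overall angle {overall} outside range of motion +-{rom} rad"
        )
    fracs = np.array([j.contribution_fraction for j in model.joints])
    return fracs * overall


def segment_transforms(
    model: NeckModel, joint_angles: np.ndarray | None = None
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """World affine transform (R, t) of every segment for a posture.

    ``joint_angles`` has shape (n_joints, 3), ordered like ``model.joints``;
    None means neutral. A local point p of segment s maps to ``R @ (origin_s
    + p) + t`` — transforms act on neutral-posture world coordinates.
    """
    tf: dict[str, tuple[np.ndarray, np.ndarray]] = {
        name: (np.eye(3), np.zeros(3)) for name in model.root_segments()
    }
    if joint_angles is None:
        joint_angles = np.zeros((len(model.joints), 3))
    joint_angles = np.asarray(joint_angles, dtype=float)
    remaining = [j for j in model.joints]
    while remaining:
        progressed = False
        for j in list(remaining):
            if j.parent_segment in tf:
                rp, tp = tf[j.parent_segment]
                rj = joint_rotation(j, joint_angles[model.joint_index[j.name]])
                # child: p -> Rp @ (c + Rj (p - c)) + tp
                r = rp @ rj
                t = rp @ (j.center - rj @ j.center) + tp
                tf[j.child_segment] = (r, t)
                remaining.remove(j)
                progressed = True
        if not progressed:  # pragma: no cover - caught by validate()
            raise ModelValidationError("joint chain is not a connected tree")
    return tf


def pose_points(
    model: NeckModel,
    transforms: dict[str, tuple[np.ndarray, np.ndarray]],
    segments: list[str],
    neutral_world: np.ndarray,
) -> np.ndarray:
    """Apply per-segment transforms to neutral-world points."""
    out = np.empty_like(neutral_world)
    for i, (seg, p) in enumerate(zip(segments, neutral_world)):
        r, t = transforms[seg]
        out[i] = r @ p + t
    return out


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def model_to_dict(model: NeckModel) -> dict:
    return {
        "format": "anthroneck-model",
        "version": 1,
        "gender": model.gender,
        "reference_anthropometry": asdict(model.reference_anthropometry),
        "range_of_motion": list(model.range_of_motion),
        "segments": [
            {
                "name": s.name,
                "parent_joint": s.parent_joint,
                "origin": s.origin.tolist(),
                "axes": s.axes.tolist(),
                "mass": s.mass,
                "com": s.com.tolist(),
                "inertia": s.inertia.tolist(),
            }
            for s in model.segments.values()
        ],
        "joints": [
            {
                "name": j.name,
                "center": j.center.tolist(),
                "parent_segment": j.parent_segment,
                "child_segment": j.child_segment,
                "contribution_fraction": j.contribution_fraction.tolist(),
                "dof_axes": j.dof_axes.tolist(),
            }
            for j in model.joints
        ],
        "fascicles": [
            {
                "name": f.name,
                "group": f.group,
                "side": f.side,
                "f_max": f.f_max,
                "optimal_fiber_length": f.optimal_fiber_length,
                "tendon_slack_length": f.tendon_slack_length,
                "nodes": [
                    {"attached_segment": n.attached_segment, "position": n.position.tolist()}
                    for n in f.nodes
                ],
            }
            for f in model.fascicles
        ],
        "landmarks": [
            {
                "name": lm.name,
                "position": lm.position.tolist(),
                "attached_segment": lm.attached_segment,
            }
            for lm in model.landmarks.values()
        ],
        "metadata": model.metadata,
    }


def model_from_dict(data: dict) -> NeckModel:
    try:
        model = NeckModel(
            gender=data["gender"],
            segments={
                s["name"]: Segment(
                    name=s["name"],
                    parent_joint=s["parent_joint"],
                    origin=s["origin"],
                    axes=s.get("axes", np.eye(3)),
                    mass=s["mass"],
                    com=s["com"],
                    inertia=s["inertia"],
                )
                for s in data["segments"]
            },
            joints=[
                Joint(
                    name=j["name"],
                    center=j["center"],
                    parent_segment=j["parent_segment"],
                    child_segment=j["child_segment"],
                    contribution_fraction=j["contribution_fraction"],
                    dof_axes=j.get("dof_axes", np.eye(3)),
                )
                for j in data["joints"]
            ],
            fascicles=[
                MuscleFascicle(
                    name=f["name"],
                    group=f["group"],
                    side=f["side"],
                    f_max=f["f_max"],
                    optimal_fiber_length=f["optimal_fiber_length"],
                    tendon_slack_length=f["tendon_slack_length"],
                    nodes=[
                        MuscleNode(attached_segment=n["attached_segment"], position=n["position"])
                        for n in f["nodes"]
                    ],
                )
                for f in data["fascicles"]
            ],
            landmarks={
                lm["name"]: Landmark(
                    name=lm["name"],
                    position=lm["position"],
                    attached_segment=lm["attached_segment"],
                )
                for lm in data["landmarks"]
            },
            reference_anthropometry=AnthropometryFeatures(**data["reference_anthropometry"]),
            range_of_motion=tuple(data.get("range_of_motion", DEFAULT_RANGE_OF_MOTION)),
            metadata=data.get("metadata", {}),
        )
    except KeyError as exc:
        raise ModelValidationError(f"model file missing required field: {exc}") from exc
    model.validate()
    return model


def save_model(model: NeckModel, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def load_model(path) -> NeckModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model file not found: {path}")
    return model_from_dict(json.loads(path.read_text()))


def build_default_model(gender: str = "male", config: dict | None = None) -> NeckModel:
    """The packaged synthetic 50th-percentile model for one gender.

    The male model is constructed from the documented synthetic geometry
    (vertebral centres stacked along z, attachments on neck-radius
    cylinders) with the published original maximum isometric forces; the
    female model is derived from it by anthropometric scaling plus a uniform
    force rescale to the published female/male total-muscle-volume ratio.
    """
    from . import _geometry

    tables._check_gender(gender)
    male = _geometry.build_male_model(config or {})
    if gender == "male":
        return male
    from .scaling import derive_female_model

    return derive_female_model(male)
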