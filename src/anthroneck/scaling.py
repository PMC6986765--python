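"""Anthropometric scaling of calibrated neck models.

Segments are scaled with per-segment XYZ factors derived from four body
measurements: cervical segments take s_x = s_y = the neck-circumference
ratio and s_z = the neck-length ratio; the skull is scaled isotropically
with the stature ratio; the torso (and any other segment) takes s_z = the
stature ratio and lateral factors sqrt(mass ratio / stature ratio), which
keeps its volume consistent with the body-mass ratio.

Muscle scaling follows the nodal-volume law: each path node carries the
volume factor s_vi = s_x s_y s_z of its segment; a fascicle's volume factor
is the characteristic-length-weighted mean s_v = sum_i (l_i / L) s_vi, its
length factor is s_L = L / L0, fiber and tendon slack lengths scale with
s_L, and the maximum isometric force scales with the PCSA factor
s_c = s_v / s_L.

Scaled models remember their reference (base) model and the cumulative
factors; re-scaling composes the factors and rebuilds from the base, so
scaling by F then element-wise 1/F is exactly the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import tables
from .model import AnthropometryFeatures, NeckModel
from .muscles import muscle_volume, node_char_lengths

CERVICAL_SEGMENTS = ("C1", "C2", "C3", "C4", "C5", "C6", "C7")
FEMALE_MALE_VOLUME_RATIO_SOURCE = ("female", "male")  # Table columns used below


@dataclass
class ScaleFactors:
    """Per-segment-class XYZ scale factors."""

    neck_xy: float = 1.0
    neck_z: float = 1.0
    skull: float = 1.0
    torso_xy: float = 1.0
    torso_z: float = 1.0
    #: populated by apply_scaling: per-fascicle {s_L, s_v, s_c}
    muscle_factors: dict = field(default_factory=dict)

    def for_segment(self, name: str) -> np.ndarray:
        if name in CERVICAL_SEGMENTS:
            return np.array([self.neck_xy, self.neck_xy, self.neck_z])
        if name == "skull":
            return np.array([self.skull, self.skull, self.skull])
        return np.array([self.torso_xy, self.torso_xy, self.torso_z])

    def per_segment(self, model: NeckModel) -> dict[str, np.ndarray]:
        return {name: self.for_segment(name) for name in model.segments}

    def validate(self) -> None:
        for v in (self.neck_xy, self.neck_z, self.skull, self.torso_xy, self.torso_z):
            if not v > 0:
                raise ValueError(f"scale factors must be > 0, got {v}")


def segment_scale_factors(
    features: AnthropometryFeatures, reference: AnthropometryFeatures
) -> ScaleFactors:
    """Scale factors mapping a reference anthropometry to target features."""
    features.validate()
    reference.validate()
    height = features.height_m / reference.height_m
    mass = features.body_mass_kg / reference.body_mass_kg
    sf = ScaleFactors(
        neck_xy=features.neck_circumference_cm / reference.neck_circumference_cm,
        neck_z=features.neck_length_cm / reference.neck_length_cm,
        skull=height,
        torso_xy=float(np.sqrt(mass / height)),
        torso_z=height,
    )
    sf.validate()
    return sf


def muscle_scale_factors(
    base_points: np.ndarray,
    scaled_points: np.ndarray,
    per_node_volume_factors: np.ndarray,
) -> tuple[float, float, float]:
    """(s_L, s_v, s_c) for one fascicle.

    s_v weights the nodal volume factors by l_i / L computed on the base
    geometry (l_i = half the incident edge lengths).
    """
    l = node_char_lengths(base_points)
    l0 = float(np.linalg.norm(np.diff(base_points, axis=0), axis=1).sum())
    l1 = float(np.linalg.norm(np.diff(scaled_points, axis=0), axis=1).sum())
    if l1 <= 0:
        raise ValueError("scaled fascicle has zero length")
    s_l = l1 / l0
    s_v = float((l / l0) @ per_node_volume_factors)
    return s_l, s_v, s_v / s_l


def _scale_inertia_tensor(inertia: np.ndarray, s: np.ndarray, mass_ratio: float) -> np.ndarray:
    """Affine transform of a COM-frame inertia tensor under XYZ scaling.

    Works through the second-moment matrix P = tr(I)/2 * Id - I, whose
    components scale as P_ab -> s_a s_b P_ab times the mass ratio.
    """
    p = 0.5 * np.trace(inertia) * np.eye(3) - inertia
    p = p * np.outer(s, s) * mass_ratio
    return np.trace(p) * np.eye(3) - p


def scale_inertia(segment, factors: np.ndarray, density_ratio: float = 1.0):
    """Scaled copy of a segment's inertial properties (affine approximation).

    Mass picks up s_x s_y s_z times the density ratio; the inertia tensor is
    transformed through its second moments; COM scales componentwise.
    """
    import copy

    s = np.asarray(factors, dtype=float)
    seg = copy.deepcopy(segment)
    vol_ratio = float(np.prod(s)) * density_ratio
    seg.com = segment.com * s
    seg.mass = segment.mass * vol_ratio
    seg.inertia = _scale_inertia_tensor(segment.inertia, s, vol_ratio)
    return seg


def _base_of(model: NeckModel) -> tuple[NeckModel, dict[str, np.ndarray]]:
    base = getattr(model, "scale_base", None)
    if base is None:
        return model, {name: np.ones(3) for name in model.segments}
    cum = {name: np.asarray(v, dtype=float) for name, v in
           model.metadata.get("cumulative_scale", {}).items()}
    for name in base.segments:
        cum.setdefault(name, np.ones(3))
    return base, cum


def apply_scaling(
    model: NeckModel,
    factors: ScaleFactors,
    total_mass: float | None = None,
) -> NeckModel:
    """Scale a model's skeleton, inertia, landmarks and muscles.

    Joint centres move with their parent segment; each segment's local
    geometry scales about its own origin, which keeps the chain connected.
    With ``total_mass`` given, a uniform density recalibration rescales all
    segment masses so they sum to it. Scaling always recomputes from the
    model's reference (base) model with composed factors, so inverse
    factors recover the base exactly.
    """
    factors.validate()
    base, cum = _base_of(model)
    eff = {name: cum[name] * factors.for_segment(name) for name in base.segments}

    scaled = base.copy()
    # segment origins / joint centres, root first
    new_origin: dict[str, np.ndarray] = {}
    for name in base.root_segments():
        new_origin[name] = base.segments[name].origin.copy()
    remaining = list(base.joints)
    new_center: dict[str, np.ndarray] = {}
    while remaining:
        for j in list(remaining):
            if j.parent_segment in new_origin:
                sp = eff[j.parent_segment]
                po = base.segments[j.parent_segment].origin
                c = new_origin[j.parent_segment] + sp * (j.center - po)
                new_center[j.name] = c
                child = j.child_segment
                sc = eff[child]
                new_origin[child] = c + sc * (base.segments[child].origin - j.center)
                remaining.remove(j)

    density_ratio = 1.0
    if total_mass is not None:
        raw_total = sum(
            seg.mass * float(np.prod(eff[name])) for name, seg in base.segments.items()
        )
        density_ratio = total_mass / raw_total

    for name, seg in scaled.segments.items():
        s = eff[name]
        bseg = base.segments[name]
        seg.origin = new_origin[name]
        seg.com = bseg.com * s
        vol_ratio = float(np.prod(s)) * density_ratio
        seg.mass = bseg.mass * vol_ratio
        seg.inertia = _scale_inertia_tensor(bseg.inertia, s, vol_ratio)
    for j, bj in zip(scaled.joints, base.joints):
        j.center = new_center[j.name]
    for lm, blm in zip(scaled.landmarks.values(), base.landmarks.values()):
        lm.position = blm.position * eff[lm.attached_segment]

    factors.muscle_factors = {}
    for f, bf in zip(scaled.fascicles, base.fascicles):
        segs = [n.attached_segment for n in bf.nodes]
        base_pts = base.world_nodes(bf)
        for n, bn in zip(f.nodes, bf.nodes):
            n.position = bn.position * eff[n.attached_segment]
        scaled_pts = np.array(
            [new_origin[s_] + n.position for s_, n in zip(segs, f.nodes)]
        )
        node_factors = np.array([float(np.prod(eff[s_])) for s_ in segs])
        s_l, s_v, s_c = muscle_scale_factors(base_pts, scaled_pts, node_factors)
        f.f_max = bf.f_max * s_c
        f.optimal_fiber_length = bf.optimal_fiber_length * s_l
        f.tendon_slack_length = bf.tendon_slack_length * s_l
        factors.muscle_factors[f.name] = {"s_L": s_l, "s_v": s_v, "s_c": s_c}

    scaled.metadata = dict(scaled.metadata)
    scaled.metadata["cumulative_scale"] = {k: v.tolist() for k, v in eff.items()}
    scaled.scale_base = base  # runtime link; not serialized
    return scaled


def scale_muscle(fascicle, base_points: np.ndarray, per_node_factors: np.ndarray):
    """Scaled copy of one fascicle given its nodes' XYZ factors.

    Node positions scale componentwise (all about a common origin); Hill
    parameters follow the s_L / s_c laws.
    """
    import copy

    f = copy.deepcopy(fascicle)
    per_node_factors = np.asarray(per_node_factors, dtype=float)
    scaled_pts = base_points * per_node_factors
    for n, p_base, p_new in zip(f.nodes, base_points, scaled_pts):
        n.position = n.position + (p_new - p_base)
    s_l, s_v, s_c = muscle_scale_factors(
        base_points, scaled_pts, np.prod(per_node_factors, axis=1)
    )
    f.f_max = fascicle.f_max * s_c
    f.optimal_fiber_length = fascicle.optimal_fiber_length * s_l
    f.tendon_slack_length = fascicle.tendon_slack_length * s_l
    return f


# ---------------------------------------------------------------------------
# Percentile model generation
# ---------------------------------------------------------------------------

@dataclass
class PercentileSpec:
    gender: str
    percentile: int
    features: AnthropometryFeatures = field(init=False)

    def __post_init__(self):
        table = tables.percentile_table(self.gender)
        if self.percentile not in table.index:
            raise ValueError(
                f"unknown percentile {self.percentile}; expected one of "
                f"{list(table.index)}"
            )
        row = table.loc[self.percentile]
        self.features = AnthropometryFeatures(
            height_m=float(row["stature_m"]),
            body_mass_kg=float(row["body_mass_kg"]),
            neck_circumference_cm=float(row["neck_circumference_cm"]),
            neck_length_cm=float(row["neck_length_cm"]),
        )


def generate_percentile_model(base: NeckModel, gender: str, percentile: int) -> NeckModel:
    """Scale a 50th-percentile model to a named percentile's anthropometry."""
    spec = PercentileSpec(gender=gender, percentile=percentile)
    if gender != base.gender:
        raise ValueError(
            f"percentile gender {gender!r} does not match the base model "
            f"({base.gender!r})"
        )
    factors = segment_scale_factors(spec.features, base.reference_anthropometry)
    scaled = apply_scaling(base, factors, total_mass=spec.features.body_mass_kg)
    scaled.reference_anthropometry = spec.features
    scaled.metadata["percentile"] = {"gender": gender, "percentile": percentile}
    return scaled


def derive_female_model(male: NeckModel, recalibrate_config=None) -> NeckModel:
    """Derive the 50th-percentile female model from the male model.

    Geometry and inertia scale to the female reference anthropometry; all
    maximum isometric forces are then rescaled by one common factor so the
    total muscle volume matches the published female/male volume ratio.
    With ``recalibrate_config`` given, the result is additionally
    recalibrated against the female strength targets.
    """
    from ._geometry import FEMALE_REFERENCE

    factors = segment_scale_factors(FEMALE_REFERENCE, male.reference_anthropometry)
    female = apply_scaling(male, factors, total_mass=FEMALE_REFERENCE.body_mass_kg)
    female.gender = "female"
    female.reference_anthropometry = FEMALE_REFERENCE
    # uniform strength rescale to the published total-volume ratio
    male_total = sum(muscle_volume(f) for f in male.fascicles)
    target_total = male_total * (
        tables.total_muscle_volume("female") / tables.total_muscle_volume("male")
    )
    current_total = sum(muscle_volume(f) for f in female.fascicles)
    ratio = target_total / current_total
    for f in female.fascicles:
        f.f_max *= ratio
    if hasattr(female, "scale_base"):
        del female.scale_base  # forces changed; no longer a pure rescale of the base
    female.metadata.pop("cumulative_scale", None)
    female.metadata["derived_from"] = "male-50th"
    if recalibrate_config is not None:
        from .calibration import StrengthTargets, calibrate

        result = calibrate(
            female, StrengthTargets.from_tables("female"), recalibrate_config
        )
        return result.model
    return female


def symmetrize(model: NeckModel) -> NeckModel:
    """Replace mirrored fascicle quantities by left/right averages.

    Idempotent; raises on unpaired sided fascicles.
    """
    out = model.copy()
    pairs = out.paired_fascicles()
    mirror = np.array([1.0, -1.0, 1.0])
    for left, right in pairs:
        if len(left.nodes) != len(right.nodes):
            raise ValueError(f"pair {left.base_name!r}: node counts differ")
        f_mean = 0.5 * (left.f_max + right.f_max)
        ofl = 0.5 * (left.optimal_fiber_length + right.optimal_fiber_length)
        tsl = 0.5 * (left.tendon_slack_length + right.tendon_slack_length)
        left.f_max = right.f_max = f_mean
        left.optimal_fiber_length = right.optimal_fiber_length = ofl
        left.tendon_slack_length = right.tendon_slack_length = tsl
        for ln, rn in zip(left.nodes, right.nodes):
            mean_left = 0.5 * (ln.position + mirror * rn.position)
            ln.position = mean_left
            rn.position = mirror * mean_left
    if hasattr(out, "scale_base"):
        del out.scale_base
    return out


def sweep_strengths(
    base: NeckModel,
    gender: str,
    percentiles: tuple[int, ...] = tables.PERCENTILES,
    modes: tuple[str, ...] = tables.MODES,
    residual_tolerance: float | None = None,
) -> pd.DataFrame:
    """Strength of every percentile model per mode (no recalibration)."""
    from .strength import DEFAULT_RESIDUAL_TOLERANCE, evaluate_strengths

    tol = DEFAULT_RESIDUAL_TOLERANCE if residual_tolerance is None else residual_tolerance
    rows = []
    for p in percentiles:
        m = generate_percentile_model(base, gender, p)
        res = evaluate_strengths(m, modes=modes, residual_tolerance=tol)
        rows.append({"percentile": p, **res.magnitudes})
    return pd.DataFrame(rows).set_index("percentile")
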