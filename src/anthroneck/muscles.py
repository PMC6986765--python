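"""Musculotendon geometry and mechanics: path lengths, tendon-excursion
moment arms, volumes/PCSAs and group volume fractions.

Fascicles are polylines of straight segments between nodes; there are no
wrapping surfaces. Moment arms follow the tendon-excursion definition
r_ij = -dL_i/dtheta_j, evaluated by central finite differences, so that a
muscle tension f produces joint torque tau_j = sum_i r_ij f_i.
"""

from __future__ import annotations

import numpy as np

from . import tables
from .model import MuscleFascicle, NeckModel, segment_transforms

# re-exported container type: the fascicle is defined with the model core
__all__ = [
    "MuscleFascicle",
    "musculotendon_length",
    "all_lengths",
    "moment_arm_matrix",
    "node_char_lengths",
    "muscle_volume",
    "pcsa",
    "group_volume_fractions",
]

DEFAULT_SPECIFIC_TENSION = 35.0  # N/cm^2
FD_STEP = 1e-5  # rad, central-difference step for moment arms


def _polyline_length(points: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def musculotendon_length(
    model: NeckModel, fascicle: MuscleFascicle, posture: np.ndarray | None = None
) -> float:
    """Total path length (m) of a fascicle in a given posture.

    ``posture`` is an (n_joints, 3) array of per-joint angles (rad); None
    means neutral.
    """
    neutral = model.world_nodes(fascicle)
    if posture is None:
        return _polyline_length(neutral)
    tf = segment_transforms(model, posture)
    segs = [n.attached_segment for n in fascicle.nodes]
    posed = np.array([tf[s][0] @ p + tf[s][1] for s, p in zip(segs, neutral)])
    return _polyline_length(posed)


def all_lengths(model: NeckModel, posture: np.ndarray | None = None) -> np.ndarray:
    """Path lengths of every fascicle, vectorized over one posture."""
    tf = segment_transforms(model, posture) if posture is not None else None
    out = np.empty(len(model.fascicles))
    for i, f in enumerate(model.fascicles):
        pts = model.world_nodes(f)
        if tf is not None:
            segs = [n.attached_segment for n in f.nodes]
            pts = np.array([tf[s][0] @ p + tf[s][1] for s, p in zip(segs, pts)])
        out[i] = _polyline_length(pts)
    return out


def moment_arm_matrix(
    model: NeckModel, posture: np.ndarray | None = None, step: float = FD_STEP
) -> np.ndarray:
    """Tendon-excursion moment arms, shape (n_fascicles, n_joints * 3).

    Column order is joint-major: (joint 0 dof x, y, z, joint 1 dof x, ...),
    with joints ordered as in ``model.joints`` (inferior to superior).
    """
    nj = len(model.joints)
    base = np.zeros((nj, 3)) if posture is None else np.asarray(posture, float).copy()
    r = np.empty((len(model.fascicles), nj * 3))
    for j in range(nj):
        for d in range(3):
            plus = base.copy()
            plus[j, d] += step
            minus = base.copy()
            minus[j, d] -= step
            dl = all_lengths(model, plus) - all_lengths(model, minus)
            r[:, 3 * j + d] = -dl / (2.0 * step)
    return r


def node_char_lengths(points: np.ndarray) -> np.ndarray:
    """Characteristic length per node: half of its incident edge lengths.

    Endpoints get half of their single edge; the sum equals the path length.
    """
    edges = np.linalg.norm(np.diff(points, axis=0), axis=1)
    l = np.zeros(len(points))
    l[:-1] += edges / 2.0
    l[1:] += edges / 2.0
    return l


def pcsa(fascicle: MuscleFascicle, specific_tension: float = DEFAULT_SPECIFIC_TENSION) -> float:
    """Physiological cross-sectional area in cm^2."""
    if not specific_tension > 0:
        raise ValueError(f"specific tension must be > 0, got {specific_tension}")
    return fascicle.f_max / specific_tension


def muscle_volume(
    fascicle: MuscleFascicle, specific_tension: float = DEFAULT_SPECIFIC_TENSION
) -> float:
    """Muscle volume in cm^3: PCSA times optimal fiber length."""
    return pcsa(fascicle, specific_tension) * fascicle.optimal_fiber_length * 100.0


def group_volume_fractions(
    model: NeckModel,
    specific_tension: float = DEFAULT_SPECIFIC_TENSION,
    groups: tuple[str, ...] | None = None,
) -> dict[str, float]:
    """Per-group share of total muscle volume (fractions summing to 1).

    With ``groups`` given, the fractions are renormalized over those groups
    only (e.g. the sixteen published groups, excluding the added rectus
    capitis flexors).
    """
    vol: dict[str, float] = {}
    for f in model.fascicles:
        if f.group not in tables.ALL_GROUPS:
            raise ValueError(f"fascicle {f.name}: unknown group {f.group!r}")
        vol[f.group] = vol.get(f.group, 0.0) + muscle_volume(f, specific_tension)
    if groups is not None:
        vol = {g: vol.get(g, 0.0) for g in groups}
    total = sum(vol.values())
    return {g: v / total for g, v in vol.items()}
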