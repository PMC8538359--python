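"""Lower-limb reference geometry measured from a femur mesh and landmarks.

Implements the preoperative measurements a revision-knee planner relies
on: the femoral anatomical axis by Moreland's two-point construction, the
femoral head centre by least-squares sphere fitting (the 3-D analogue of
the radiographic Mose-circle template), the femoral mechanical axis, the
surgical trans-epicondylar axis (TEA), the posterior condylar angle (PCA)
and the signed coronal (varus/valgus) deviation of a joint line.

Sign conventions, fixed here because the source descriptions are verbal:
varus deviation is positive; a PCA is positive when the posterior
condyles are internally rotated relative to the surgical TEA.  Both signs
flip under mirroring of the whole geometry, as chirality demands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.optimize import least_squares

from .errors import ExtentError, GeometryError, MeasurementError, ValidationError
from .femur import LandmarkSet
from .geometry import ray_cast_first_hit, section_centroid, unit

__all__ = [
    "AxisLine",
    "AxisReport",
    "fit_femoral_head_center",
    "moreland_anatomical_axis",
    "mechanical_axis",
    "surgical_tea",
    "posterior_condylar_angle",
    "coronal_deviation",
    "probe_condyles",
    "measure_axes",
]

#: Moreland's second defining point sits this far above the knee-joint
#: surface, along the proximal-distal direction (the "10 cm" rule).
MORELAND_OFFSET_MM = 100.0


@dataclass
class AxisLine:
    """A 3-D line: a point on it and a unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if not np.isfinite(n) or abs(n - 1.0) > 1e-6:
            self.direction = unit(self.direction)

    def angle_to(self, other: "AxisLine") -> float:
        """Unsigned angle between the two line directions, degrees, in [0, 90]."""
        c = abs(float(np.dot(self.direction, other.direction)))
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass
class AxisReport:
    anatomical_axis: AxisLine
    mechanical_axis_FMA: AxisLine
    surgical_TEA: AxisLine
    posterior_condylar_line: AxisLine
    pca: float  # degrees, internal rotation of condyles positive
    coronal_deviation: float  # degrees, varus positive

    def __post_init__(self):
        if not np.isfinite(self.pca) or abs(self.pca) >= 45:
            raise ValidationError(f"pca out of range: {self.pca}")
        if not np.isfinite(self.coronal_deviation) or abs(self.coronal_deviation) >= 45:
            raise ValidationError(f"coronal_deviation out of range: {self.coronal_deviation}")

    def to_dict(self) -> dict:
        def line(a: AxisLine):
            return {"point": a.point.tolist(), "direction": a.direction.tolist()}

        return {
            "anatomical_axis": line(self.anatomical_axis),
            "mechanical_axis_FMA": line(self.mechanical_axis_FMA),
            "surgical_TEA": line(self.surgical_TEA),
            "posterior_condylar_line": line(self.posterior_condylar_line),
            "pca_deg": self.pca,
            "coronal_deviation_deg": self.coronal_deviation,
        }


# ---------------------------------------------------------------------------
# femoral head centre


def fit_femoral_head_center(points: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Least-squares sphere fit: returns (centre, radius, rms residual).

    An algebraic linear fit provides the start; a geometric (orthogonal
    distance) refinement polishes it.  Requires at least 10 points that
    are not all coplanar.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 10:
        raise ValidationError("fit_femoral_head_center needs >= 10 points (N, 3)")
    centered = pts - pts.mean(axis=0)
    if np.linalg.svd(centered, compute_uv=False)[-1] < 1e-9 * np.abs(pts).max():
        raise GeometryError("sphere fit: points are (nearly) coplanar")

    # algebraic: || x ||^2 = 2 c.x + (r^2 - ||c||^2)
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.einsum("ij,ij->i", pts, pts)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c0 = sol[:3]
    r0 = float(np.sqrt(max(sol[3] + c0 @ c0, 1e-12)))

    def residual(x):
        return np.linalg.norm(pts - x[:3], axis=1) - x[3]

    fit = least_squares(residual, np.append(c0, r0), xtol=1e-12, ftol=1e-12, gtol=1e-12)
    center, radius = fit.x[:3], float(fit.x[3])
    rms = float(np.sqrt(np.mean(residual(fit.x) ** 2)))
    return center, radius, rms


# ---------------------------------------------------------------------------
# axes


def moreland_anatomical_axis(mesh: trimesh.Trimesh, landmarks: LandmarkSet) -> AxisLine:
    """Femoral anatomical axis by Moreland's two defining points.

    The proximal-distal direction is the line from the superior aspect of
    the femoral head to the distal medial condyle.  P1 is the slice
    centroid at half the proximal-to-distal length (this centres the point
    both medio-laterally and antero-posteriorly); P2 is the slice centroid
    100 mm above the knee-joint surface (the most distal condylar point).
    The axis is oriented distal -> proximal.
    """
    u = unit(landmarks.femoral_head_center - landmarks.distal_condyle_medial)
    s = mesh.vertices @ u
    s_min, s_max = float(s.min()), float(s.max())
    s_mid = 0.5 * (s_min + s_max)
    s_p2 = s_min + MORELAND_OFFSET_MM
    if s_p2 >= s_max - 1.0:
        raise ExtentError(
            f"mesh spans only {s_max - s_min:.1f} mm along the femur; "
            f"cannot place Moreland's point {MORELAND_OFFSET_MM:.0f} mm above the joint"
        )
    p1 = section_centroid(mesh, plane_origin=u * s_mid, plane_normal=u)
    p2 = section_centroid(mesh, plane_origin=u * s_p2, plane_normal=u)
    if np.linalg.norm(p1 - p2) < 1.0:
        raise MeasurementError("Moreland points nearly coincident")
    return AxisLine(point=p2, direction=unit(p1 - p2))


def mechanical_axis(head_center: np.ndarray, knee_center: np.ndarray) -> AxisLine:
    """Femoral mechanical axis: knee centre -> femoral head centre."""
    head_center = np.asarray(head_center, dtype=float)
    knee_center = np.asarray(knee_center, dtype=float)
    if np.linalg.norm(head_center - knee_center) <= 50.0:
        raise GeometryError(
            "mechanical axis endpoints must be more than 50 mm apart"
        )
    return AxisLine(point=knee_center, direction=unit(head_center - knee_center))


def surgical_tea(landmarks: LandmarkSet) -> AxisLine:
    """Surgical trans-epicondylar axis, oriented medial -> lateral."""
    med = landmarks.medial_epicondyle_sulcus
    lat = landmarks.lateral_epicondyle_prominence
    if np.linalg.norm(lat - med) < 10.0:
        raise GeometryError("epicondylar landmarks closer than 10 mm")
    return AxisLine(point=med, direction=unit(lat - med))


def _transverse_basis(landmarks: LandmarkSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(t, a, m): TEA direction projected into the transverse plane, its
    in-plane normal a = m x t, and the proximal mechanical direction m."""
    m = mechanical_axis(
        landmarks.femoral_head_center, landmarks.trochlear_notch_center
    ).direction
    t_raw = landmarks.lateral_epicondyle_prominence - landmarks.medial_epicondyle_sulcus
    t_proj = t_raw - (t_raw @ m) * m
    if np.linalg.norm(t_proj) < 1e-6:
        raise GeometryError("TEA is parallel to the mechanical axis")
    t = unit(t_proj)
    return t, np.cross(m, t), m


def posterior_condylar_angle(landmarks: LandmarkSet) -> float:
    """Signed PCA in degrees, measured in the transverse plane (normal =
    mechanical axis) between the posterior condylar tangent and the
    surgical TEA.  Positive when the posterior condyles are internally
    rotated relative to the TEA."""
    t, a, m = _transverse_basis(landmarks)
    p_raw = landmarks.posterior_condyle_lateral - landmarks.posterior_condyle_medial
    p_proj = p_raw - (p_raw @ m) * m
    if np.linalg.norm(p_proj) < 1e-6:
        raise GeometryError("posterior condylar line parallel to mechanical axis")
    p = unit(p_proj)
    return float(np.degrees(np.arctan2(p @ a, p @ t)))


def coronal_deviation(mech: AxisLine, joint_line: AxisLine) -> float:
    """Signed departure of a joint line from perpendicularity to the
    mechanical axis, degrees; varus positive.

    ``joint_line`` must be oriented medial -> lateral and ``mech`` distal
    -> proximal; a proximally deficient medial side (joint line climbing
    proximally toward medial) then reads as positive varus.
    """
    j = unit(joint_line.direction)
    m = unit(mech.direction)
    c = float(j @ m)
    if abs(c) > np.cos(np.radians(5.0)):
        raise GeometryError("joint line nearly parallel to the mechanical axis")
    return float(-np.degrees(np.arcsin(np.clip(c, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# mesh probing and the assembled report


def probe_condyles(mesh: trimesh.Trimesh, landmarks: LandmarkSet) -> LandmarkSet:
    """Relocate the four condylar contact landmarks onto the actual bone
    surface by ray casting, keeping their in-plane positions.

    On an intact femur this returns the input landmarks (within mesh
    tolerance); on a defective femur the returned points track the
    receded surface, so axis measurements reflect the bone loss.
    """
    out = landmarks.copy()
    m = mechanical_axis(
        landmarks.femoral_head_center, landmarks.trochlear_notch_center
    ).direction
    t, a, _ = _transverse_basis(landmarks)
    post_dir = unit(a if a @ (landmarks.trochlear_notch_center
                              - 0.5 * (landmarks.posterior_condyle_medial
                                       + landmarks.posterior_condyle_lateral)) > 0 else -a)

    for name in ("distal_condyle_medial", "distal_condyle_lateral"):
        p = getattr(landmarks, name)
        origin = p - 20.0 * m
        t_hit = ray_cast_first_hit(mesh, origin, m)[0]
        if np.isnan(t_hit):
            raise MeasurementError(f"distal probe ray missed the bone at {name}")
        setattr(out, name, origin + t_hit * m)
    for name in ("posterior_condyle_medial", "posterior_condyle_lateral"):
        p = getattr(landmarks, name)
        origin = p - 20.0 * post_dir
        t_hit = ray_cast_first_hit(mesh, origin, post_dir)[0]
        if np.isnan(t_hit):
            raise MeasurementError(f"posterior probe ray missed the bone at {name}")
        setattr(out, name, origin + t_hit * post_dir)
    return out


def measure_axes(
    mesh: trimesh.Trimesh, landmarks: LandmarkSet, probe_surface: bool = True
) -> AxisReport:
    """Assemble the full axis report for a femur.

    With ``probe_surface`` the condylar tangent lines are taken from the
    actual bone surface (so defects shift the PCA and the coronal
    deviation); otherwise the landmark positions are used as given.
    """
    lm = probe_condyles(mesh, landmarks) if probe_surface else landmarks
    mech = mechanical_axis(lm.femoral_head_center, lm.trochlear_notch_center)
    joint = AxisLine(
        point=lm.distal_condyle_medial,
        direction=lm.distal_condyle_lateral - lm.distal_condyle_medial,
    )
    return AxisReport(
        anatomical_axis=moreland_anatomical_axis(mesh, landmarks),
        mechanical_axis_FMA=mech,
        surgical_TEA=surgical_tea(lm),
        posterior_condylar_line=AxisLine(
            point=lm.posterior_condyle_medial,
            direction=lm.posterior_condyle_lateral - lm.posterior_condyle_medial,
        ),
        pca=posterior_condylar_angle(lm),
        coronal_deviation=coronal_deviation(mech, joint),
    )
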