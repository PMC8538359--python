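"""Component placement, gap measurement and augment planning.

The planning sequence mirrors what a surgeon does on the virtual model:

1. ``place_component`` — pose the femoral component perpendicular to the
   mechanical axis, rotationally aligned to the surgical TEA, with its
   distal bone-facing plane at the joint-line target distance (default
   42.5 mm, the middle of the accepted 40-45 mm window below the adductor
   tubercle).
2. ``measure_gaps`` — ray-cast from the planned distal and posterior cut
   planes to the residual bone over small condylar patches; a positive
   gap is a bone deficit that the component must fill.
3. ``solve_augments`` — convert the four gaps into a symmetric distal
   augment (joint-line restoration) and asymmetric distal / posterior
   augments (coronal / rotational restoration), quantised to whole
   millimetres.
4. ``verify_restoration`` — check that the augmented component drives the
   residual gaps, the implant coronal deviation and the PCA deviation to
   (near) zero and keeps the joint line inside the 40-45 mm window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .axes import (
    AxisLine,
    AxisReport,
    mechanical_axis,
    moreland_anatomical_axis,
    posterior_condylar_angle,
    surgical_tea,
)
from .errors import MeasurementError, PlacementError, ValidationError
from .femur import LandmarkSet
from .geometry import disc_samples, ray_cast_first_hit, round_half_up, unit
from .spacer import AugmentSpec, SpacerParams, build_spacer_mesh

__all__ = [
    "PlacementPose",
    "GapMeasurements",
    "AugmentPlan",
    "RestorationResult",
    "CohortSummary",
    "SCENARIO_LABELS",
    "JOINTLINE_WINDOW_MM",
    "place_component",
    "measure_gaps",
    "solve_augments",
    "augments_from_plan",
    "verify_restoration",
    "classify_scenario",
    "summarize_cohort",
    "plan_spacer",
    "PlanReport",
]

#: Acceptable distance window, adductor tubercle to joint line, mm.
JOINTLINE_WINDOW_MM = (40.0, 45.0)
#: Default target: middle of the window.
DEFAULT_JOINTLINE_TARGET_MM = 42.5

SCENARIO_LABELS = ("JOINT_LINE", "CORONAL", "ROTATIONAL", "NONE")


@dataclass
class PlacementPose:
    """Rigid pose of the component frame in the bone frame."""

    rotation: np.ndarray  # 3x3, columns = (M-L, anterior, proximal) axes
    translation: np.ndarray  # origin: distal plane z=0, posterior plane y=0
    achieved_jointline_distance: float

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValidationError("rotation must be a 3x3 orthonormal matrix")
        if np.linalg.det(R) < 0:
            raise ValidationError("rotation must be proper (det +1)")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float)

    @property
    def ml_axis(self) -> np.ndarray:
        return self.rotation[:, 0]

    @property
    def anterior_axis(self) -> np.ndarray:
        return self.rotation[:, 1]

    @property
    def proximal_axis(self) -> np.ndarray:
        return self.rotation[:, 2]


@dataclass
class GapMeasurements:
    """Signed bone deficits (mm) at the four condylar facets."""

    g_dist_med: float
    g_dist_lat: float
    g_post_med: float
    g_post_lat: float

    def __post_init__(self):
        for nm in ("g_dist_med", "g_dist_lat", "g_post_med", "g_post_lat"):
            v = float(getattr(self, nm))
            if not np.isfinite(v) or abs(v) >= 30:
                raise ValidationError(f"gap {nm} out of range: {v}")
            setattr(self, nm, v)

    def as_tuple(self):
        return (self.g_dist_med, self.g_dist_lat, self.g_post_med, self.g_post_lat)


@dataclass
class AugmentPlan:
    """Augment thicknesses, quantised to ``rounding_step``."""

    symmetric_distal: float = 0.0
    asymmetric_distal: tuple[str | None, float] = (None, 0.0)
    asymmetric_posterior: tuple[str | None, float] = (None, 0.0)
    rounding_step: float = 1.0

    def __post_init__(self):
        for nm, v in (
            ("symmetric_distal", self.symmetric_distal),
            ("asymmetric_distal", self.asymmetric_distal[1]),
            ("asymmetric_posterior", self.asymmetric_posterior[1]),
        ):
            if v < 0:
                raise ValidationError(f"{nm} must be >= 0 (got {v})")
            if abs(v / self.rounding_step - round(v / self.rounding_step)) > 1e-9:
                raise ValidationError(f"{nm} must be a multiple of rounding_step")

    @property
    def is_empty(self) -> bool:
        return (
            self.symmetric_distal == 0
            and self.asymmetric_distal[1] == 0
            and self.asymmetric_posterior[1] == 0
        )

    def to_dict(self) -> dict:
        return {
            "symmetric_distal_mm": self.symmetric_distal,
            "asymmetric_distal": {"side": self.asymmetric_distal[0], "mm": self.asymmetric_distal[1]},
            "asymmetric_posterior": {"side": self.asymmetric_posterior[0], "mm": self.asymmetric_posterior[1]},
            "rounding_step_mm": self.rounding_step,
        }


@dataclass
class CohortSummary:
    n: int
    counts: dict
    percentages: dict  # nearest-integer percent per label

    def to_dict(self) -> dict:
        return {"n": self.n, "counts": self.counts, "percentages": self.percentages}


# ---------------------------------------------------------------------------


def _component_basis(landmarks: LandmarkSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(ml, ant, prox): orthonormal component axes from the bone's axes.

    ``prox`` is the mechanical axis, ``ml`` the TEA projected into the
    transverse plane, ``ant`` their right-handed completion oriented
    anteriorly (toward the trochlear notch from the posterior condyles).
    """
    prox = mechanical_axis(
        landmarks.femoral_head_center, landmarks.trochlear_notch_center
    ).direction
    t_raw = landmarks.lateral_epicondyle_prominence - landmarks.medial_epicondyle_sulcus
    t_proj = t_raw - (t_raw @ prox) * prox
    if np.linalg.norm(t_proj) < 1e-6:
        raise PlacementError("surgical TEA parallel to the mechanical axis")
    ml = unit(t_proj)
    ant = np.cross(prox, ml)
    post_mid = 0.5 * (landmarks.posterior_condyle_medial + landmarks.posterior_condyle_lateral)
    a_ref = landmarks.trochlear_notch_center - post_mid
    if ant @ a_ref < 0:
        ml, ant = -ml, -ant
    return ml, ant, prox


def place_component(
    bone: trimesh.Trimesh,
    landmarks: LandmarkSet,
    params: SpacerParams,
    target_distance: float = DEFAULT_JOINTLINE_TARGET_MM,
) -> PlacementPose:
    """Pose the component: distal facet perpendicular to the mechanical
    axis, medio-lateral axis parallel to the surgical TEA in the
    transverse plane, distal plane at ``target_distance`` below the
    adductor tubercle along the mechanical axis."""
    lo, hi = JOINTLINE_WINDOW_MM
    if not (lo <= target_distance <= hi):
        raise ValidationError(
            f"target_distance must lie in [{lo}, {hi}] mm (got {target_distance})"
        )
    ml, ant, prox = _component_basis(landmarks)

    dc_mid = 0.5 * (landmarks.distal_condyle_medial + landmarks.distal_condyle_lateral)
    post_mid = 0.5 * (landmarks.posterior_condyle_medial + landmarks.posterior_condyle_lateral)
    origin = (
        (ml @ dc_mid) * ml
        + (ant @ post_mid) * ant
        + (prox @ landmarks.adductor_tubercle - target_distance) * prox
    )
    achieved = float(prox @ (landmarks.adductor_tubercle - origin))
    return PlacementPose(
        rotation=np.column_stack([ml, ant, prox]),
        translation=origin,
        achieved_jointline_distance=achieved,
    )


def _patch_gap(
    bone: trimesh.Trimesh,
    center: np.ndarray,
    ray_dir: np.ndarray,
    basis: tuple[np.ndarray, np.ndarray],
    patch_radius: float,
    name: str,
    standoff: float = 15.0,
) -> float:
    offs = disc_samples(patch_radius)
    origins = (
        center[None, :]
        + offs[:, :1] * basis[0][None, :]
        + offs[:, 1:2] * basis[1][None, :]
        - standoff * ray_dir[None, :]
    )
    t = ray_cast_first_hit(bone, origins, ray_dir)
    if np.isnan(t).any():
        raise MeasurementError(f"gap measurement ray missed the bone at {name}")
    return float(np.mean(t) - standoff)


def measure_gaps(
    bone: trimesh.Trimesh,
    landmarks: LandmarkSet,
    pose: PlacementPose,
    params: SpacerParams,
    patch_radius: float = 5.0,
) -> GapMeasurements:
    """Mean signed distance from each planned cut plane to the bone
    surface over a patch centred on the corresponding condylar landmark.

    Distal gaps are measured along the mechanical axis (the distal cut
    normal), posterior gaps along the anterior (into-bone) normal of the
    posterior cut plane.  Each patch plane passes through its native
    condylar landmark, so the gap is the per-condyle bone deficit
    relative to the native condylar surface: positive = bone loss,
    intact bone reads 0.
    """
    ml, ant, prox = pose.ml_axis, pose.anterior_axis, pose.proximal_axis

    gaps = {}
    for key, lm_name, plane_n, basis in (
        ("g_dist_med", "distal_condyle_medial", prox, (ml, ant)),
        ("g_dist_lat", "distal_condyle_lateral", prox, (ml, ant)),
        ("g_post_med", "posterior_condyle_medial", ant, (ml, prox)),
        ("g_post_lat", "posterior_condyle_lateral", ant, (ml, prox)),
    ):
        center = getattr(landmarks, lm_name)
        gaps[key] = _patch_gap(bone, center, plane_n, basis, patch_radius, lm_name)
    return GapMeasurements(**gaps)


def solve_augments(gaps: GapMeasurements, rounding_step: float = 1.0) -> AugmentPlan:
    """Turn the four condylar gaps into an augment plan.

    The shared (minimum) distal deficit is restored by a symmetric distal
    augment; side-to-side differences by asymmetric distal/posterior
    augments on the deficient side.  Thicknesses are rounded half-up to
    ``rounding_step`` (default whole millimetres).
    """
    sym_raw = max(0.0, min(gaps.g_dist_med, gaps.g_dist_lat))
    sym = round_half_up(sym_raw, rounding_step)

    d_diff = gaps.g_dist_med - gaps.g_dist_lat
    d_mag = round_half_up(abs(d_diff), rounding_step)
    asym_d = ("medial" if d_diff > 0 else "lateral", d_mag) if d_mag > 0 else (None, 0.0)

    p_diff = gaps.g_post_med - gaps.g_post_lat
    p_mag = round_half_up(abs(p_diff), rounding_step)
    asym_p = ("medial" if p_diff > 0 else "lateral", p_mag) if p_mag > 0 else (None, 0.0)

    return AugmentPlan(
        symmetric_distal=sym,
        asymmetric_distal=asym_d,
        asymmetric_posterior=asym_p,
        rounding_step=rounding_step,
    )


def augments_from_plan(plan: AugmentPlan, base: AugmentSpec | None = None) -> AugmentSpec:
    """Pad thicknesses realising an augment plan on the component."""
    base = base or AugmentSpec()
    t_dm = t_dl = plan.symmetric_distal
    side, mag = plan.asymmetric_distal
    if side == "medial":
        t_dm += mag
    elif side == "lateral":
        t_dl += mag
    t_pm = t_pl = 0.0
    side, mag = plan.asymmetric_posterior
    if side == "medial":
        t_pm = mag
    elif side == "lateral":
        t_pl = mag
    return AugmentSpec(
        t_dist_med=t_dm,
        t_dist_lat=t_dl,
        t_post_med=t_pm,
        t_post_lat=t_pl,
        A_MC=base.A_MC,
        A_LC=base.A_LC,
    )


@dataclass
class RestorationResult:
    """Outcome of re-checking alignment with the augmented component."""

    axis_report: AxisReport
    residual_gaps: GapMeasurements
    achieved_jointline_distance: float
    coronal_deviation: float  # implant joint line vs mechanical axis, deg
    pca_deviation: float  # shift of effective condylar line vs native, deg
    component_mesh: trimesh.Trimesh = field(repr=False, default=None)


def verify_restoration(
    bone: trimesh.Trimesh,
    landmarks: LandmarkSet,
    pose: PlacementPose,
    params: SpacerParams,
    plan: AugmentPlan,
) -> RestorationResult:
    """Re-measure alignment with the augment pads applied.

    The augmented component mesh is built (and checked) with the plan's
    pad thicknesses; each pad advances its bone-facing surface toward the
    bone, so the residual deficit at a condyle is the measured gap minus
    the pad thickness there.  Residual side-to-side differences tilt the
    implant joint line (coronal deviation) or rotate the effective
    posterior condylar line (PCA deviation); a residual symmetric deficit
    lets the component settle proximally, shortening the joint-line
    distance.
    """
    spec = augments_from_plan(plan)
    component = build_spacer_mesh(params, spec)

    gaps = measure_gaps(bone, landmarks, pose, params)
    r_dm = gaps.g_dist_med - spec.t_dist_med
    r_dl = gaps.g_dist_lat - spec.t_dist_lat
    r_pm = gaps.g_post_med - spec.t_post_med
    r_pl = gaps.g_post_lat - spec.t_post_lat
    residual = GapMeasurements(r_dm, r_dl, r_pm, r_pl)

    ml = pose.ml_axis
    span_d = abs(ml @ (landmarks.distal_condyle_lateral - landmarks.distal_condyle_medial))
    span_p = abs(ml @ (landmarks.posterior_condyle_lateral - landmarks.posterior_condyle_medial))
    coronal = float(np.degrees(np.arctan2(r_dm - r_dl, span_d)))
    pca_dev = float(np.degrees(np.arctan2(r_pl - r_pm, span_p)))

    settle = max(0.0, min(r_dm, r_dl))
    achieved = pose.achieved_jointline_distance - settle

    mech = mechanical_axis(landmarks.femoral_head_center, landmarks.trochlear_notch_center)
    report = AxisReport(
        anatomical_axis=moreland_anatomical_axis(bone, landmarks),
        mechanical_axis_FMA=mech,
        surgical_TEA=surgical_tea(landmarks),
        posterior_condylar_line=AxisLine(
            point=landmarks.posterior_condyle_medial,
            direction=landmarks.posterior_condyle_lateral - landmarks.posterior_condyle_medial,
        ),
        pca=posterior_condylar_angle(landmarks) + pca_dev,
        coronal_deviation=coronal,
    )
    return RestorationResult(
        axis_report=report,
        residual_gaps=residual,
        achieved_jointline_distance=achieved,
        coronal_deviation=coronal,
        pca_deviation=pca_dev,
        component_mesh=component,
    )


def classify_scenario(plan: AugmentPlan, threshold: float = 1.0) -> str:
    """Map an augment plan to its clinical scenario.

    Symmetric distal -> JOINT_LINE (joint-line restoration), asymmetric
    distal -> CORONAL (alignment restoration), asymmetric posterior ->
    ROTATIONAL (rotational restoration).  With several components above
    ``threshold`` the largest wins; exact ties break by the fixed priority
    CORONAL > ROTATIONAL > JOINT_LINE.
    """
    candidates = {
        "JOINT_LINE": plan.symmetric_distal,
        "CORONAL": plan.asymmetric_distal[1],
        "ROTATIONAL": plan.asymmetric_posterior[1],
    }
    flagged = {k: v for k, v in candidates.items() if v > threshold}
    if not flagged:
        return "NONE"
    best = max(flagged.values())
    for label in ("CORONAL", "ROTATIONAL", "JOINT_LINE"):  # tie priority
        if flagged.get(label) == best:
            return label
    raise AssertionError("unreachable")


def summarize_cohort(labels: list[str]) -> CohortSummary:
    """Counts and nearest-integer percentages per scenario label."""
    if not labels:
        raise ValidationError("summarize_cohort requires a non-empty label list")
    unknown = set(labels) - set(SCENARIO_LABELS)
    if unknown:
        raise ValidationError(f"unknown scenario labels: {sorted(unknown)}")
    n = len(labels)
    counts = {lab: labels.count(lab) for lab in SCENARIO_LABELS}
    pct = {lab: int(round_half_up(100.0 * c / n)) for lab, c in counts.items()}
    return CohortSummary(n=n, counts=counts, percentages=pct)


# ---------------------------------------------------------------------------
# one-call pipeline


@dataclass
class PlanReport:
    pose: PlacementPose
    gaps: GapMeasurements
    plan: AugmentPlan
    label: str
    restoration: RestorationResult

    def to_dict(self) -> dict:
        return {
            "pose": {
                "rotation": self.pose.rotation.tolist(),
                "translation": self.pose.translation.tolist(),
                "achieved_jointline_distance_mm": self.pose.achieved_jointline_distance,
            },
            "gaps_mm": {
                "distal_medial": self.gaps.g_dist_med,
                "distal_lateral": self.gaps.g_dist_lat,
                "posterior_medial": self.gaps.g_post_med,
                "posterior_lateral": self.gaps.g_post_lat,
            },
            "plan": self.plan.to_dict(),
            "scenario": self.label,
            "restoration": {
                "achieved_jointline_distance_mm": self.restoration.achieved_jointline_distance,
                "coronal_deviation_deg": self.restoration.coronal_deviation,
                "pca_deviation_deg": self.restoration.pca_deviation,
                "axis_report": self.restoration.axis_report.to_dict(),
            },
        }


def plan_spacer(
    bone: trimesh.Trimesh,
    landmarks: LandmarkSet,
    params: SpacerParams | None = None,
    target_distance: float = DEFAULT_JOINTLINE_TARGET_MM,
    rounding_step: float = 1.0,
    classification_threshold: float = 1.0,
) -> PlanReport:
    """Full planning pipeline: place, measure, solve, verify, classify."""
    params = params or SpacerParams()
    pose = place_component(bone, landmarks, params, target_distance)
    gaps = measure_gaps(bone, landmarks, pose, params)
    plan = solve_augments(gaps, rounding_step)
    restoration = verify_restoration(bone, landmarks, pose, params, plan)
    label = classify_scenario(plan, classification_threshold)
    return PlanReport(pose=pose, gaps=gaps, plan=plan, label=label, restoration=restoration)
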