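"""Synthetic femur generator with injectable condylar bone defects.

Builds a stylised but metrically controlled femur — sphere head, tilted
cylindrical shaft and neck, and a bicondylar distal block — together with
the named anatomical landmarks that drive every axis computation
downstream.  The geometry is deliberately simple: the planning mathematics
only needs correct landmark relations and locally flat distal/posterior
condylar surfaces so that a segmental defect has a well-defined depth.

Canonical frame (right femur): +z proximal along the mechanical axis,
+x lateral, +y anterior, units mm.  A left femur is the exact mirror of
the right one through the sagittal plane x = 0.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import trimesh

from .errors import GeometryError, ValidationError
from .geometry import mirror_mesh_x

__all__ = [
    "FemurSpec",
    "DefectSpec",
    "LandmarkSet",
    "CohortMember",
    "DEFECT_KINDS",
    "NOTCH_WIDTH",
    "NOTCH_HEIGHT",
    "generate_femur",
    "apply_defect",
    "preset_case",
    "generate_cohort",
]

DEFECT_KINDS = (
    "none",
    "distal_symmetric",
    "distal_medial",
    "distal_lateral",
    "posterior_medial",
    "posterior_lateral",
)

# Fixed proportions of the distal block (mm unless noted).  The
# intercondylar notch is 20 mm wide and 12 mm high; the posterior condyles
# are rounded with a 15 mm radius, the anterior-distal transition with
# 12 mm.  Condylar landmarks sit at +-0.3 W (distal) and +-W/3 (posterior)
# so the default 75 mm wide femur has a 45 mm distal and 50 mm posterior
# intercondylar span.
NOTCH_WIDTH = 20.0
NOTCH_HEIGHT = 12.0
R_POSTERIOR = 15.0
R_ANTERIOR_DISTAL = 12.0


@dataclass
class FemurSpec:
    """Degrees of freedom of the synthetic femur."""

    side: str = "right"
    total_length: float = 420.0
    head_radius: float = 24.0
    head_center_offset: np.ndarray | None = None  # from proximal shaft end
    shaft_radius: float = 14.0
    condylar_width_ML: float = 75.0
    condylar_depth_AP: float = 60.0
    anatomical_mechanical_angle: float = 6.0  # degrees, coronal plane
    native_pca: float = 3.0  # degrees
    tubercle_to_jointline: float = 42.5  # mm along the mechanical axis
    mesh_resolution: int = 16  # segments per 90 degree arc
    seed: int = 0

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be 'left' or 'right', got {self.side!r}")
        for name in (
            "total_length",
            "head_radius",
            "shaft_radius",
            "condylar_width_ML",
            "condylar_depth_AP",
            "tubercle_to_jointline",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.total_length <= self.condylar_width_ML:
            raise ValidationError(
                "total_length must exceed condylar_width_ML "
                f"({self.total_length} <= {self.condylar_width_ML})"
            )
        if not (0 <= self.native_pca < 15):
            raise ValidationError(f"native_pca must be in [0, 15), got {self.native_pca}")
        if self.mesh_resolution < 8:
            raise ValidationError(
                f"mesh_resolution must be >= 8, got {self.mesh_resolution}"
            )
        if self.head_center_offset is not None:
            self.head_center_offset = np.asarray(self.head_center_offset, dtype=float)
            if self.head_center_offset.shape != (3,):
                raise ValidationError("head_center_offset must be a 3-vector")

    @property
    def block_height(self) -> float:
        """Proximal extent of the condylar block above the joint line."""
        return self.tubercle_to_jointline + 7.5


@dataclass
class DefectSpec:
    """A segmental condylar bone defect: a plane cut of given depth."""

    kind: str = "none"
    depth: float = 0.0

    def __post_init__(self):
        if self.kind not in DEFECT_KINDS:
            raise ValidationError(f"kind must be one of {DEFECT_KINDS}, got {self.kind!r}")
        if self.depth < 0:
            raise ValidationError(f"depth must be >= 0, got {self.depth}")
        if (self.depth == 0) != (self.kind == "none"):
            raise ValidationError("depth must be 0 exactly when kind is 'none'")


LANDMARK_NAMES = (
    "femoral_head_center",
    "adductor_tubercle",
    "lateral_epicondyle_prominence",
    "medial_epicondyle_sulcus",
    "trochlear_notch_center",
    "distal_condyle_medial",
    "distal_condyle_lateral",
    "posterior_condyle_medial",
    "posterior_condyle_lateral",
)


@dataclass
class LandmarkSet:
    """Named anatomical points, all (3,) arrays in mm."""

    femoral_head_center: np.ndarray
    adductor_tubercle: np.ndarray
    lateral_epicondyle_prominence: np.ndarray
    medial_epicondyle_sulcus: np.ndarray
    trochlear_notch_center: np.ndarray
    distal_condyle_medial: np.ndarray
    distal_condyle_lateral: np.ndarray
    posterior_condyle_medial: np.ndarray
    posterior_condyle_lateral: np.ndarray

    def __post_init__(self):
        for name in LANDMARK_NAMES:
            p = np.asarray(getattr(self, name), dtype=float)
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise ValidationError(f"landmark {name} must be a finite 3-vector")
            setattr(self, name, p)
        sep = np.linalg.norm(
            self.lateral_epicondyle_prominence - self.medial_epicondyle_sulcus
        )
        if sep <= 10.0:
            raise ValidationError(
                f"epicondylar landmarks separated by {sep:.2f} mm (need > 10)"
            )
        # medial/lateral pairs must straddle the sagittal midplane (the
        # plane through the trochlear notch normal to the epicondylar line)
        ml_dir = (
            self.lateral_epicondyle_prominence - self.medial_epicondyle_sulcus
        ) / sep
        for med, lat in (
            (self.distal_condyle_medial, self.distal_condyle_lateral),
            (self.posterior_condyle_medial, self.posterior_condyle_lateral),
        ):
            s_med = (med - self.trochlear_notch_center) @ ml_dir
            s_lat = (lat - self.trochlear_notch_center) @ ml_dir
            if s_med * s_lat >= 0:
                raise ValidationError(
                    "medial and lateral condylar landmarks must lie on "
                    "opposite sides of the sagittal midplane"
                )

    def items(self) -> Iterator[tuple[str, np.ndarray]]:
        for name in LANDMARK_NAMES:
            yield name, getattr(self, name)

    def to_dict(self) -> dict:
        return {name: [float(c) for c in p] for name, p in self.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        unknown = set(d) - set(LANDMARK_NAMES)
        if unknown:
            raise ValidationError(f"unknown landmark keys: {sorted(unknown)}")
        missing = set(LANDMARK_NAMES) - set(d)
        if missing:
            raise ValidationError(f"missing landmark keys: {sorted(missing)}")
        return cls(**{k: np.asarray(v, dtype=float) for k, v in d.items()})

    def mirror_x(self) -> "LandmarkSet":
        out = {}
        for name, p in self.items():
            q = p.copy()
            q[0] *= -1.0
            out[name] = q
        return LandmarkSet(**out)

    def copy(self) -> "LandmarkSet":
        return LandmarkSet(**{name: p.copy() for name, p in self.items()})


@dataclass
class CohortMember:
    mesh: trimesh.Trimesh
    landmarks: LandmarkSet
    true_label: str  # "case1" | "case2" | "case3"
    defect: DefectSpec
    spec: FemurSpec


# ---------------------------------------------------------------------------
# condylar block construction


def _block_cross_section(spec: FemurSpec, z_floor: float) -> np.ndarray:
    """Closed (y, z) ring of the condylar block at one medio-lateral
    station.  Fixed topology for every station so the block can be swept
    as a single watertight tube."""
    ap = spec.condylar_depth_AP
    h = spec.block_height
    ra, rp = R_ANTERIOR_DISTAL, R_POSTERIOR
    res = spec.mesh_resolution
    ne = max(4, res // 2)

    def seg(p0, p1, n):
        t = np.linspace(0.0, 1.0, n, endpoint=False)[:, None]
        return np.asarray(p0) + t * (np.asarray(p1) - np.asarray(p0))

    pts = []
    # anterior face, top corner down to the fillet start
    pts.append(seg((ap / 2, h), (ap / 2, z_floor + ra), ne))
    # anterior-distal quarter fillet
    th = np.linspace(0.0, np.pi / 2, res, endpoint=False)
    ca = np.array([ap / 2 - ra, z_floor + ra])
    pts.append(ca + ra * np.stack([np.cos(th), -np.sin(th)], axis=1))
    # distal floor (the joint-line surface, locally flat)
    pts.append(seg((ap / 2 - ra, z_floor), (-ap / 2 + rp, z_floor), ne))
    # posterior condylar quarter round; its posterior-most point is the
    # posterior condylar tangent position y = -AP/2
    cp = np.array([-ap / 2 + rp, z_floor + rp])
    pts.append(cp + rp * np.stack([-np.sin(th), -np.cos(th)], axis=1))
    # posterior face up, then flat top back to the start
    pts.append(seg((-ap / 2, z_floor + rp), (-ap / 2, h), ne))
    pts.append(seg((-ap / 2, h), (ap / 2, h), ne))
    return np.vstack(pts)


def _notch_floor(x: np.ndarray, spec: FemurSpec) -> np.ndarray:
    """Distal floor height: 0 on the condyles, raised smoothly to the
    intercondylar notch height between them."""
    z = np.zeros_like(x)
    inside = np.abs(x) < NOTCH_WIDTH / 2
    z[inside] = NOTCH_HEIGHT * np.cos(np.pi * x[inside] / NOTCH_WIDTH) ** 2
    return z


def _sweep_tube(stations: np.ndarray, rings: np.ndarray) -> trimesh.Trimesh:
    """Stitch per-station closed rings into a capped watertight tube.

    ``stations``: (S,) x positions; ``rings``: (S, N, 2) (y, z) loops.
    """
    S, N, _ = rings.shape
    verts = np.empty((S * N + 2, 3))
    for s in range(S):
        verts[s * N : (s + 1) * N, 0] = stations[s]
        verts[s * N : (s + 1) * N, 1:] = rings[s]
    # cap centroids
    verts[-2] = [stations[0], *rings[0].mean(axis=0)]
    verts[-1] = [stations[-1], *rings[-1].mean(axis=0)]

    faces = []
    for s in range(S - 1):
        a = s * N + np.arange(N)
        b = s * N + (np.arange(N) + 1) % N
        c = a + N
        d = b + N
        faces.append(np.stack([a, b, d], axis=1))
        faces.append(np.stack([a, d, c], axis=1))
    # end fans
    i0 = np.arange(N)
    j0 = (np.arange(N) + 1) % N
    faces.append(np.stack([np.full(N, S * N), j0, i0], axis=1))
    base = (S - 1) * N
    faces.append(np.stack([np.full(N, S * N + 1), base + i0, base + j0], axis=1))
    mesh = trimesh.Trimesh(vertices=verts, faces=np.vstack(faces), process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def _build_condylar_block(spec: FemurSpec) -> trimesh.Trimesh:
    w = spec.condylar_width_ML
    nx = 4 * spec.mesh_resolution + 1
    stations = np.linspace(-w / 2, w / 2, nx)
    floors = _notch_floor(stations, spec)
    rings = np.stack([_block_cross_section(spec, zf) for zf in floors])
    return _sweep_tube(stations, rings)


def _build_landmarks(spec: FemurSpec) -> LandmarkSet:
    """Landmarks of the canonical right femur, consistent with the mesh."""
    w = spec.condylar_width_ML
    ap = spec.condylar_depth_AP
    h = spec.block_height
    t_pca = np.tan(np.radians(spec.native_pca))
    head_z = spec.total_length - spec.head_radius
    return LandmarkSet(
        femoral_head_center=np.array([0.0, 0.0, head_z]),
        adductor_tubercle=np.array([-w / 2, -5.0, spec.tubercle_to_jointline]),
        # epicondyles on the end-cap faces; their anteroposterior offset
        # realises the native posterior condylar angle relative to the
        # posterior condylar tangent line (which runs parallel to x)
        lateral_epicondyle_prominence=np.array([w / 2, -(w / 2) * t_pca, 0.5 * h]),
        medial_epicondyle_sulcus=np.array([-w / 2, (w / 2) * t_pca, 0.5 * h]),
        trochlear_notch_center=np.array([0.0, 0.0, NOTCH_HEIGHT + 3.0]),
        distal_condyle_medial=np.array([-0.3 * w, 0.0, 0.0]),
        distal_condyle_lateral=np.array([0.3 * w, 0.0, 0.0]),
        # on the flat posterior tangent plane, just above the condylar round
        posterior_condyle_medial=np.array([-w / 3, -ap / 2, R_POSTERIOR + 5.0]),
        posterior_condyle_lateral=np.array([w / 3, -ap / 2, R_POSTERIOR + 5.0]),
    )


def generate_femur(spec: FemurSpec) -> tuple[trimesh.Trimesh, LandmarkSet]:
    """Generate a watertight synthetic femur mesh and its landmark set.

    The distal condylar surfaces lie exactly ``spec.tubercle_to_jointline``
    distal of the adductor tubercle along the mechanical axis (the +z axis
    of the canonical frame), and the epicondylar landmarks realise
    ``spec.native_pca`` against the posterior condylar tangent.
    Deterministic: the geometry is fully parametric and ``spec.seed`` is
    only recorded for provenance.
    """
    block = _build_condylar_block(spec)

    # shaft, tilted by the anatomical-mechanical angle in the coronal plane
    alpha = np.radians(spec.anatomical_mechanical_angle)
    d = np.array([np.sin(alpha), 0.0, np.cos(alpha)])
    z0 = spec.block_height - 15.0
    z1 = spec.total_length - 2.2 * spec.head_radius
    if z1 <= z0 + 120.0:
        raise ValidationError(
            "total_length too short for shaft construction (field total_length)"
        )
    p0 = np.array([0.0, 0.0, z0])
    p1 = p0 + d * (z1 - z0) / np.cos(alpha)
    shaft = trimesh.creation.cylinder(
        radius=spec.shaft_radius, segment=[p0, p1], sections=4 * spec.mesh_resolution
    )

    head_z = spec.total_length - spec.head_radius
    if spec.head_center_offset is None:
        head_c = np.array([0.0, 0.0, head_z])
    else:
        head_c = p1 + spec.head_center_offset
    head = trimesh.creation.icosphere(subdivisions=3, radius=spec.head_radius)
    head.apply_translation(head_c)

    neck = trimesh.creation.cylinder(
        radius=0.55 * spec.head_radius,
        segment=[p1, head_c],
        sections=4 * spec.mesh_resolution,
    )

    mesh = trimesh.util.concatenate([block, shaft, neck, head])
    landmarks = _build_landmarks(spec)
    if spec.head_center_offset is not None:
        landmarks.femoral_head_center = head_c.copy()

    if spec.side == "left":
        mesh = mirror_mesh_x(mesh)
        landmarks = landmarks.mirror_x()

    if not mesh.is_watertight:
        raise GeometryError("generated femur mesh is not watertight")
    return mesh, landmarks


# ---------------------------------------------------------------------------
# defects


def apply_defect(
    mesh: trimesh.Trimesh, landmarks: LandmarkSet, defect: DefectSpec
) -> trimesh.Trimesh:
    """Cut the named condylar region back by ``defect.depth``.

    Implemented as a plane cut in the generator frame: vertices of the
    named condyle beyond the cut plane are projected onto it, which keeps
    the mesh watertight, strictly reduces volume and leaves every other
    vertex untouched.  Distal defects cut along the mechanical axis,
    posterior defects along the posterior-facing normal.
    """
    if defect.kind == "none":
        return mesh.copy()
    if not mesh.is_watertight:
        raise GeometryError("apply_defect requires a watertight input mesh")

    d = float(defect.depth)
    med_sign = float(np.sign(landmarks.distal_condyle_medial[0]))
    v = mesh.vertices.copy()

    def side_mask(which: str) -> np.ndarray:
        if which == "both":
            return np.abs(v[:, 0]) > NOTCH_WIDTH / 2
        s = med_sign if which == "medial" else -med_sign
        return v[:, 0] * s > NOTCH_WIDTH / 2

    if defect.kind.startswith("distal"):
        if d >= NOTCH_HEIGHT:
            raise GeometryError(
                f"distal defect depth {d} mm reaches the intercondylar notch "
                f"(condylar thickness {NOTCH_HEIGHT} mm)"
            )
        z_joint = float(landmarks.distal_condyle_medial[2])
        z_cut = z_joint + d
        which = {"distal_symmetric": "both", "distal_medial": "medial", "distal_lateral": "lateral"}[defect.kind]
        mask = side_mask(which) & (v[:, 2] < z_cut)
        v[mask, 2] = z_cut
    else:
        if d >= R_POSTERIOR:
            raise GeometryError(
                f"posterior defect depth {d} mm exceeds the posterior condylar "
                f"thickness ({R_POSTERIOR} mm)"
            )
        y_post = float(landmarks.posterior_condyle_medial[1])
        y_cut = y_post + d
        z_guard = float(landmarks.adductor_tubercle[2]) + 10.0
        which = "medial" if defect.kind == "posterior_medial" else "lateral"
        mask = side_mask(which) & (v[:, 1] < y_cut) & (v[:, 2] < z_guard)
        v[mask, 1] = y_cut

    if not mask.any():
        raise GeometryError(f"defect {defect.kind} depth {d} cuts no material")
    out = trimesh.Trimesh(vertices=v, faces=mesh.faces.copy(), process=False)
    if not out.is_watertight:
        raise GeometryError("defect cut produced a non-watertight mesh")
    return out


_PRESETS = {
    "case1": DefectSpec("distal_symmetric", 3.0),
    "case2": DefectSpec("distal_medial", 7.0),
    "case3": DefectSpec("posterior_lateral", 8.0),
}

# scenario labels matching the planning module's classification
CASE_TO_LABEL = {"case1": "JOINT_LINE", "case2": "CORONAL", "case3": "ROTATIONAL"}


def preset_case(name: str) -> tuple[FemurSpec, DefectSpec]:
    """The three worked clinical scenarios: a 3 mm symmetric distal defect,
    a 7 mm medial distal defect, and an 8 mm posterior-lateral defect."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    return FemurSpec(), dataclasses.replace(_PRESETS[name])


def generate_cohort(
    n: int,
    scenario_mix,
    seed: int,
    depth_range: tuple[float, float] = (2.0, 10.0),
) -> list[CohortMember]:
    """Draw a synthetic patient cohort with per-patient defect scenarios.

    ``scenario_mix`` gives the case1/case2/case3 proportions (sequence or
    dict); defect depths are drawn uniformly on integer millimetres within
    ``depth_range``.  Reproducible for a fixed seed; true labels are
    returned for recovery testing.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if isinstance(scenario_mix, dict):
        probs = np.array([scenario_mix.get(c, 0.0) for c in ("case1", "case2", "case3")])
    else:
        probs = np.asarray(scenario_mix, dtype=float)
    if probs.shape != (3,) or (probs < 0).any():
        raise ValidationError("scenario_mix must be 3 non-negative proportions")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValidationError(f"scenario_mix must sum to 1 (got {probs.sum()!r})")

    rng = np.random.default_rng(seed)
    spec = FemurSpec(seed=seed)
    base_mesh, base_lm = generate_femur(spec)

    lo, hi = depth_range
    cases = ("case1", "case2", "case3")
    kinds = {"case1": "distal_symmetric", "case2": "distal_medial", "case3": "posterior_lateral"}
    members = []
    for _ in range(n):
        label = cases[rng.choice(3, p=probs)]
        depth = float(rng.integers(int(lo), int(hi) + 1))
        defect = DefectSpec(kinds[label], depth)
        mesh = apply_defect(base_mesh, base_lm, defect)
        members.append(CohortMember(mesh, base_lm.copy(), label, defect, spec))
    return members
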