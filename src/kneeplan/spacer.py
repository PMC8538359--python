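"""Parametric CAD kernel for the ALPMMA femoral spacer component.

The component is defined by a five-facet sagittal "box-cut" profile
(anterior flange, anterior chamfer, distal facet, posterior chamfer,
posterior facet) whose facet amplitudes ``A_*`` and turning angles
``theta_*`` are free parameters, an articular outer curve obtained by
offsetting the bone-facing profile by the facet thicknesses ``D1 -> D2 ->
D3`` (blended linearly in arc length across the chamfers, with circular
fillets at the joints), and a sweep across the medio-lateral size with two
condylar lobes separated by an intercondylar notch of width ``WP`` whose
posterior roof follows a circular cam-post curve of height ``HP``.
Optional augment pads (distal medial/lateral, posterior medial/lateral)
thicken the bone-facing facets to compensate segmental bone loss.

Component frame: x medio-lateral (sweep axis), y anterior, z proximal;
the distal bone-facing facet lies in the plane z = 0 and the posterior
bone-facing facet in the plane y = 0, which is what the planning module
uses to pose the component.

Conventions chosen where the source description is silent: D1 is the
anterior-flange thickness, D2 distal, D3 posterior; turning angles are
exterior angles between consecutive facets (default 45 deg each, the
classic five-cut femoral box); the cam-post curve is a circular arc of
height HP over chord WP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
import trimesh
from shapely.geometry import LineString

from .errors import GeometryError, ValidationError

__all__ = [
    "SpacerParams",
    "AugmentSpec",
    "SagittalProfile",
    "FACET_NAMES",
    "build_sagittal_profile",
    "build_spacer_mesh",
    "validate_params",
]

FACET_NAMES = ("anterior", "anterior_chamfer", "distal", "posterior_chamfer", "posterior")

# sample-region codes: 0..4 facets, 10+j the fillet following facet j
_CORNER = 10


@dataclass
class SpacerParams:
    # facet thicknesses (bone-facing to articular), mm
    D1: float = 9.0
    D2: float = 9.0
    D3: float = 9.0
    # cutting-segment amplitudes, mm (anterior ... posterior)
    A_AS: float = 30.0
    A_ACS: float = 12.0
    A_DS: float = 35.0
    A_PCS: float = 12.0
    A_PS: float = 28.0
    # turning angles between consecutive segments, degrees
    theta_AC: float = 45.0
    theta_D: float = 45.0
    theta_PC: float = 45.0
    theta_P: float = 45.0
    # cam-post / trochlear profile
    HP: float = 8.0
    WP: float = 20.0
    # overall sizing
    size_AP: float = 70.0
    size_ML: float = 75.0
    side: str = "right"
    resolution: int = 10  # samples per facet

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([self.A_AS, self.A_ACS, self.A_DS, self.A_PCS, self.A_PS])

    @property
    def thetas(self) -> np.ndarray:
        return np.array([self.theta_AC, self.theta_D, self.theta_PC, self.theta_P])


@dataclass
class AugmentSpec:
    """Augment pad thicknesses and medio-lateral amplitudes."""

    t_dist_med: float = 0.0
    t_dist_lat: float = 0.0
    t_post_med: float = 0.0
    t_post_lat: float = 0.0
    A_MC: float = 20.0  # medial condylar pad amplitude (from the medial edge)
    A_LC: float = 20.0  # lateral condylar pad amplitude

    @property
    def any_pad(self) -> bool:
        return any(t > 0 for t in (self.t_dist_med, self.t_dist_lat, self.t_post_med, self.t_post_lat))


@dataclass
class SagittalProfile:
    """Bone-facing polyline, articular outer curve and sampling metadata."""

    inner_polyline: np.ndarray  # (6, 2) facet corner points, (u, v)
    outer_curve: np.ndarray  # (N, 2) articular curve
    facet_index: np.ndarray  # (N,) region code per sample
    inner_sampled: np.ndarray = field(default=None, repr=False)  # (N, 2)
    normals: np.ndarray = field(default=None, repr=False)  # (N, 2) outward
    thickness: np.ndarray = field(default=None, repr=False)  # (N,)

    @property
    def chord(self) -> float:
        """Antero-posterior extent of the bone-facing polyline."""
        return float(np.ptp(self.inner_polyline[:, 0]))


def _rot(deg: float) -> np.ndarray:
    r = np.radians(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[c, -s], [s, c]])


def validate_params(params: SpacerParams, augments: AugmentSpec | None = None) -> list[dict]:
    """Check every invariant; returns a report and never raises.

    Each entry: ``{"check": name, "ok": bool, "message": str}``.
    """
    report = []

    def check(name, ok, message):
        report.append({"check": name, "ok": bool(ok), "message": message})

    for nm in ("D1", "D2", "D3", "A_AS", "A_ACS", "A_DS", "A_PCS", "A_PS", "WP", "size_AP", "size_ML"):
        v = getattr(params, nm)
        check(nm, v > 0, f"{nm} must be > 0 (got {v})")
    check("HP", params.HP >= 0, f"HP must be >= 0 (got {params.HP})")
    for nm in ("theta_AC", "theta_D", "theta_PC", "theta_P"):
        v = getattr(params, nm)
        check(nm, 0 < v <= 90, f"{nm} must be in (0, 90] degrees (got {v})")
    check("side", params.side in ("left", "right"), f"side must be left|right (got {params.side!r})")
    check("resolution", params.resolution >= 4, f"resolution must be >= 4 (got {params.resolution})")
    check(
        "WP_vs_ML",
        params.WP < params.size_ML,
        f"cam-post width WP ({params.WP}) must be smaller than size_ML ({params.size_ML})",
    )

    if all(r["ok"] for r in report):
        # geometric checks need a constructible profile
        try:
            prof = build_sagittal_profile(params)
            check(
                "chord_vs_AP",
                prof.chord <= params.size_AP + 1e-9,
                f"profile chord {prof.chord:.1f} mm exceeds size_AP {params.size_AP}",
            )
        except ValidationError as exc:
            check("profile_simple", False, str(exc))

    if augments is not None:
        for nm in ("t_dist_med", "t_dist_lat", "t_post_med", "t_post_lat"):
            v = getattr(augments, nm)
            check(nm, v >= 0, f"{nm} must be >= 0 (got {v})")
        for nm in ("A_MC", "A_LC"):
            v = getattr(augments, nm)
            check(
                nm,
                0 <= v <= params.size_ML / 2,
                f"{nm} must lie in [0, size_ML/2] (got {v})",
            )
    return report


def _require_valid(params: SpacerParams, augments: AugmentSpec | None = None):
    bad = [r for r in validate_params(params, augments) if not r["ok"]]
    if bad:
        raise ValidationError("; ".join(r["message"] for r in bad))


def build_sagittal_profile(params: SpacerParams) -> SagittalProfile:
    """Construct the five-facet bone-facing polyline and its offset
    articular curve.

    The polyline starts at the proximal end of the anterior flange heading
    distally and turns by each ``theta`` in sequence (clockwise in the
    (u=anterior, v=proximal) plane).  Thickness along the curve is D1 on
    the anterior facet, D2 on the distal facet, D3 on the posterior facet,
    blended linearly in arc length across the chamfers; joints carry
    circular fillets.
    """
    for nm in ("D1", "D2", "D3", "A_AS", "A_ACS", "A_DS", "A_PCS", "A_PS"):
        if getattr(params, nm) <= 0:
            raise ValidationError(f"{nm} must be > 0 (got {getattr(params, nm)})")

    amps = params.amplitudes
    dirs = [np.array([0.0, -1.0])]
    for th in params.thetas:
        dirs.append(_rot(-th) @ dirs[-1])
    dirs = np.array(dirs)

    corners = np.zeros((6, 2))
    for i in range(5):
        corners[i + 1] = corners[i] + amps[i] * dirs[i]

    # simplicity of the open polyline
    if not LineString(corners).is_simple:
        offending = []
        for i in range(5):
            for j in range(i + 2, 5):
                a = shapely.LineString(corners[i : i + 2])
                b = shapely.LineString(corners[j : j + 2])
                if a.intersects(b):
                    offending.append(f"{FACET_NAMES[i]}-{FACET_NAMES[j]}")
        raise ValidationError(
            "self-intersecting sagittal profile between facets: " + ", ".join(offending)
        )

    # re-anchor: posterior bone-facing facet -> u = 0, distal facet -> v = 0
    corners[:, 0] -= corners[4, 0]
    corners[:, 1] -= corners[2, 1]

    normals_f = np.stack([_rot(90.0) @ d for d in dirs])  # outward per facet
    t_facet = np.array([params.D1, None, params.D2, None, params.D3], dtype=object)

    r_in = 0.1 * min(params.D1, params.D2, params.D3)
    m = params.resolution
    n_arc = max(3, params.resolution // 2)

    pts, nrm, thick, region = [], [], [], []
    # thickness at the start/end of each facet (for the chamfer blends)
    t_ends = [
        (params.D1, params.D1),
        (params.D1, params.D2),
        (params.D2, params.D2),
        (params.D2, params.D3),
        (params.D3, params.D3),
    ]
    for f in range(5):
        q0, q1 = corners[f], corners[f + 1]
        trim0 = r_in * np.tan(np.radians(params.thetas[f - 1] / 2)) if f > 0 else 0.0
        trim1 = r_in * np.tan(np.radians(params.thetas[f] / 2)) if f < 4 else 0.0
        if trim0 + trim1 >= amps[f]:
            raise ValidationError(
                f"facet {FACET_NAMES[f]} amplitude {amps[f]} too small for its fillets"
            )
        d = dirs[f]
        a0 = q0 + d * trim0
        a1 = q1 - d * trim1
        s = np.linspace(0.0, 1.0, m + 1)
        seg = a0 + s[:, None] * (a1 - a0)
        t0, t1 = t_ends[f]
        # blend in arc length over the *full* facet span
        lam = (trim0 + s * (amps[f] - trim0 - trim1)) / amps[f]
        tt = t0 + lam * (t1 - t0)
        pts.append(seg)
        nrm.append(np.repeat(normals_f[f][None, :], m + 1, axis=0))
        thick.append(tt)
        region.append(np.full(m + 1, f))
        if f < 4:
            th = params.thetas[f]
            center = a1 - normals_f[f] * r_in  # on the bone side of the joint
            phis = np.linspace(0.0, th, n_arc + 2)[1:-1]
            arc_n = np.stack([_rot(-p) @ normals_f[f] for p in phis])
            pts.append(center + r_in * arc_n)
            nrm.append(arc_n)
            thick.append(np.full(len(phis), t_ends[f][1]))
            region.append(np.full(len(phis), _CORNER + f))

    pts = np.vstack(pts)
    nrm = np.vstack(nrm)
    thick = np.concatenate(thick)
    region = np.concatenate(region).astype(int)
    outer = pts + nrm * thick[:, None]

    return SagittalProfile(
        inner_polyline=corners,
        outer_curve=outer,
        facet_index=region,
        inner_sampled=pts,
        normals=nrm,
        thickness=thick,
    )


# ---------------------------------------------------------------------------
# sweep to a solid


def _lobe_shape(x: np.ndarray, params: SpacerParams) -> np.ndarray:
    """Two half-ellipse condylar bulges, zero in the notch and at the
    medio-lateral edges."""
    half_span = (params.size_ML / 2 - params.WP / 2) / 2
    centers = params.WP / 2 + half_span
    out = np.zeros_like(x)
    for c in (-centers, centers):
        m = np.abs(x - c) < half_span
        out[m] = np.maximum(out[m], np.sqrt(1.0 - ((x[m] - c) / half_span) ** 2))
    return out


def build_spacer_mesh(
    params: SpacerParams, augments: AugmentSpec | None = None
) -> trimesh.Trimesh:
    """Sweep the sagittal profile across ``size_ML`` into a watertight
    component, with condylar lobes, trochlear groove, cam-post roof and
    optional augment pads.

    Pads displace the bone-facing surface toward the bone over their
    medio-lateral amplitude (``A_MC`` from the medial edge, ``A_LC`` from
    the lateral edge), so mesh volume grows by pad thickness x footprint.
    """
    augments = augments or AugmentSpec()
    _require_valid(params, augments)
    prof = build_sagittal_profile(params)

    inner2 = prof.inner_sampled  # (N, 2) in (u=anterior, v=proximal)
    normals = prof.normals
    thick = prof.thickness
    region = prof.facet_index
    N = len(inner2)

    nx = 8 * params.resolution + 1
    stations = np.linspace(-params.size_ML / 2, params.size_ML / 2, nx)

    in_notch = np.abs(stations) < params.WP / 2
    groove = np.zeros(nx)
    groove[in_notch] = np.cos(np.pi * stations[in_notch] / params.WP) ** 2
    campost = np.zeros(nx)
    campost[in_notch] = np.sqrt(1.0 - (2.0 * stations[in_notch] / params.WP) ** 2)
    lobe = _lobe_shape(stations, params)

    anterior_r = (region == 0) | (region == _CORNER + 0)
    articular_r = np.isin(region, [1, 2, 3, _CORNER + 1, _CORNER + 2])
    roof_r = np.isin(region, [3, 4, _CORNER + 3])
    distal_pad_r = np.isin(region, [2, _CORNER + 1, _CORNER + 2])
    posterior_pad_r = np.isin(region, [4, _CORNER + 3])

    # per-station additive change of the articular offset
    extra = np.zeros((nx, N))
    extra[:, anterior_r] += (-0.15 * params.D1) * groove[:, None]
    extra[:, roof_r] += params.HP * campost[:, None]
    extra[:, articular_r] += (0.04 * params.size_ML) * lobe[:, None]

    # augment pad displacement of the bone-facing surface
    med_sign = -1.0 if params.side == "right" else 1.0
    med_mask = stations * med_sign > params.size_ML / 2 - (augments.A_MC + 1e-9)
    lat_mask = stations * med_sign < -(params.size_ML / 2 - (augments.A_LC + 1e-9))
    pad_shift = np.zeros((nx, N, 2))
    for mask, t_dist, t_post in (
        (med_mask, augments.t_dist_med, augments.t_post_med),
        (lat_mask, augments.t_dist_lat, augments.t_post_lat),
    ):
        if t_dist > 0:
            pad_shift[np.ix_(mask, distal_pad_r)] += np.array([0.0, t_dist])
        if t_post > 0:
            pad_shift[np.ix_(mask, posterior_pad_r)] += np.array([t_post, 0.0])

    inner_st = inner2[None, :, :] + pad_shift  # (nx, N, 2)
    outer_st = inner2[None, :, :] + normals[None, :, :] * (
        thick[None, :] + extra
    )[:, :, None]

    # closed ring per station: bone-facing samples forward, articular back
    rings = np.concatenate([inner_st, outer_st[:, ::-1, :]], axis=1)  # (nx, 2N, 2)

    n_ring = 2 * N
    verts = np.empty((nx * n_ring, 3))
    verts[:, 0] = np.repeat(stations, n_ring)
    verts[:, 1:] = rings.reshape(-1, 2)

    faces = []
    idx = np.arange(n_ring)
    nxt = (idx + 1) % n_ring
    for s in range(nx - 1):
        a = s * n_ring + idx
        b = s * n_ring + nxt
        c = a + n_ring
        d = b + n_ring
        faces.append(np.stack([a, b, d], axis=1))
        faces.append(np.stack([a, d, c], axis=1))
    # end caps: quad strip between corresponding inner/outer samples
    for s, flip in ((0, True), (nx - 1, False)):
        base = s * n_ring
        for i in range(N - 1):
            ii, jj = base + i, base + i + 1
            oi, oj = base + n_ring - 1 - i, base + n_ring - 2 - i
            tris = [[ii, jj, oj], [ii, oj, oi]]
            if flip:
                tris = [t[::-1] for t in tris]
            faces.extend(tris)

    mesh = trimesh.Trimesh(vertices=verts, faces=np.vstack([np.atleast_2d(f) for f in faces]), process=False)
    if mesh.volume < 0:
        mesh.invert()
    if not mesh.is_watertight:
        raise GeometryError(
            "spacer sweep produced a non-watertight mesh "
            f"(params resolution {params.resolution}; check profile validity)"
        )
    if mesh.volume <= 0:
        raise GeometryError("spacer mesh has non-positive volume")
    return mesh
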