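"""STL and JSON readers/writers plus run configuration.

All meshes travel as STL (binary or ASCII); all structured artifacts
(landmarks, spacer parameters, augment plans, axis reports, cohort
manifests) are JSON with fixed key names.  Lengths are millimetres,
angles degrees, everywhere.

Note on STL precision: the ASCII dialect round-trips vertices exactly;
the binary dialect stores float32 and is therefore only exact to about
1e-5 relative (a few 1e-5 mm at femur scale).
"""

from __future__ import annotations

import dataclasses
import json
import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

from .errors import FormatError, ValidationError
from .femur import LandmarkSet
from .spacer import AugmentSpec, SpacerParams

__all__ = [
    "read_stl",
    "write_stl",
    "read_landmarks",
    "write_landmarks",
    "read_spacer_params",
    "write_spacer_params",
    "read_augments",
    "write_json",
    "RunConfig",
]


def _validate_binary_stl(path: Path):
    size = path.stat().st_size
    if size < 84:
        raise FormatError(
            f"binary STL truncated: {size} bytes, header needs 84", byte_offset=size
        )
    with open(path, "rb") as fh:
        fh.seek(80)
        (n_tri,) = struct.unpack("<I", fh.read(4))
    expected = 84 + 50 * n_tri
    if size != expected:
        raise FormatError(
            f"binary STL facet count {n_tri} implies {expected} bytes, file has {size}",
            byte_offset=min(size, expected),
        )


def read_stl(path) -> trimesh.Trimesh:
    """Read an STL file (binary or ASCII, tolerant of CRLF endings),
    merging duplicate vertices at 1e-6 mm."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "rb") as fh:
        head = fh.read(512)
    is_ascii = head.lstrip().lower().startswith(b"solid") and b"facet" in head.lower()
    if not is_ascii:
        _validate_binary_stl(path)
    try:
        mesh = trimesh.load_mesh(str(path), file_type="stl", process=False)
    except Exception as exc:  # trimesh raises assorted types on bad input
        raise FormatError(f"cannot parse STL {path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise FormatError(f"STL {path} contains no triangles")
    mesh.merge_vertices(digits_vertex=6)
    return mesh


def write_stl(mesh: trimesh.Trimesh, path, dialect: str = "binary"):
    """Write a mesh as STL; ``dialect`` is 'binary' or 'ascii'."""
    if dialect not in ("binary", "ascii"):
        raise ValidationError(f"dialect must be 'binary' or 'ascii', got {dialect!r}")
    file_type = "stl" if dialect == "binary" else "stl_ascii"
    data = mesh.export(file_type=file_type)
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


# ---------------------------------------------------------------------------
# JSON artifacts


def write_json(obj: dict, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _load_json(path) -> dict:
    try:
        with open(path) as fh:
            return json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid JSON in {path}: {exc}", byte_offset=exc.pos) from exc


def read_landmarks(path) -> LandmarkSet:
    return LandmarkSet.from_dict(_load_json(path))


def write_landmarks(landmarks: LandmarkSet, path):
    write_json(landmarks.to_dict(), path)


def _from_dict(cls, d: dict, what: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValidationError(f"unknown {what} keys: {sorted(unknown)}")
    return cls(**d)


def read_spacer_params(path) -> SpacerParams:
    return _from_dict(SpacerParams, _load_json(path), "spacer parameter")


def write_spacer_params(params: SpacerParams, path):
    write_json(dataclasses.asdict(params), path)


def read_augments(path) -> AugmentSpec:
    return _from_dict(AugmentSpec, _load_json(path), "augment")


# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Run-wide configuration shared by the CLI subcommands."""

    seed: int = 0
    units: str = "mm"  # fixed; present for provenance in outputs
    jointline_target: float = 42.5
    rounding_step: float = 1.0
    classification_threshold: float = 1.0
    mesh_resolution: int = 16
    out_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self):
        if self.units != "mm":
            raise ValidationError("units are fixed to mm")
        if not (40.0 <= self.jointline_target <= 45.0):
            raise ValidationError(
                f"jointline_target must be in [40, 45] mm (got {self.jointline_target})"
            )
        if self.rounding_step <= 0:
            raise ValidationError("rounding_step must be > 0")
        if self.classification_threshold < 0:
            raise ValidationError("classification_threshold must be >= 0")
        if self.mesh_resolution < 8:
            raise ValidationError("mesh_resolution must be >= 8")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return _from_dict(cls, _load_json(path), "config")

    def digest(self) -> str:
        import hashlib

        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
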