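"""Axisymmetric cosine-throat stenosis geometry and STL export.

The lumen surface is a tube of revolution whose radius follows

    R(z) = R0 - (dR/2) * (1 + cos(2 pi (z - zc) / Ls))   inside the throat,
    R(z) = R0                                            elsewhere,

with dR = R0 * sigma, so the minimum radius R0*(1 - sigma) sits at the
throat centre zc and the profile meets the parent vessel with zero slope
(C1 continuity) at zc +/- Ls/2.  Units are millimetres throughout, the
convention expected by downstream meshing tools; a scale factor converts to
metres for SI workflows.

Meshes are plain surfaces of revolution: nz axial stations x ntheta
circumferential samples, each quad split into two triangles, optionally
fan-capped at the ends.  ``trimesh`` provides the mesh container and STL
(binary or ASCII) read/write.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "StenosisGeometry",
    "radius_profile",
    "axial_stations",
    "generate_surface",
    "write_stl",
    "read_stl",
]


@dataclass(frozen=True)
class StenosisGeometry:
    """Tube-with-throat geometry description (all lengths in mm).

    ``n_axial``/``n_circumferential`` control mesh resolution; when
    ``n_axial`` is None a locally refined axial grid is chosen (spacing
    <= Ls/20 inside the throat, <= 1 mm outside).
    """

    total_length_L: float = 30.0
    base_radius_R0: float = 1.5
    throat_length_Ls: float = 5.0
    throat_center_zc: float = 15.0
    sigma: float = 0.0
    n_axial: int | None = None
    n_circumferential: int = 64
    capped_ends: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.sigma < 1.0):
            raise ValueError(f"sigma must lie in [0, 1), got {self.sigma!r}")
        if self.total_length_L <= 0 or self.base_radius_R0 <= 0 or self.throat_length_Ls <= 0:
            raise ValueError("lengths and radius must be strictly positive")
        lo = self.throat_center_zc - self.throat_length_Ls / 2
        hi = self.throat_center_zc + self.throat_length_Ls / 2
        if lo < 0 or hi > self.total_length_L:
            raise ValueError("throat window zc +/- Ls/2 must lie inside [0, L]")
        if self.n_axial is not None and self.n_axial < 2:
            raise ValueError("n_axial must be >= 2")
        if self.n_circumferential < 3:
            raise ValueError("n_circumferential must be >= 3")


def radius_profile(z: float | np.ndarray, geom: StenosisGeometry) -> float | np.ndarray:
    """Lumen radius at axial position(s) ``z`` (mm)."""
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr < 0) or np.any(z_arr > geom.total_length_L):
        raise ValueError(f"z must lie in [0, {geom.total_length_L}] mm")
    dR = geom.base_radius_R0 * geom.sigma
    inside = np.abs(z_arr - geom.throat_center_zc) <= geom.throat_length_Ls / 2
    r = np.full_like(z_arr, geom.base_radius_R0)
    if dR > 0:
        phase = 2.0 * math.pi * (z_arr - geom.throat_center_zc) / geom.throat_length_Ls
        r = np.where(inside, geom.base_radius_R0 - (dR / 2.0) * (1.0 + np.cos(phase)), r)
    if np.ndim(z) == 0:
        return float(r)
    return r


def axial_stations(geom: StenosisGeometry) -> np.ndarray:
    """Axial sample positions: uniform if ``n_axial`` is set, else refined.

    The refined grid keeps spacing <= Ls/20 within the throat window and
    <= 1 mm outside, with the window edges included so the profile kink-free
    junctions are sampled exactly.
    """
    if geom.n_axial is not None:
        return np.linspace(0.0, geom.total_length_L, geom.n_axial)
    lo = geom.throat_center_zc - geom.throat_length_Ls / 2
    hi = geom.throat_center_zc + geom.throat_length_Ls / 2
    segments = []
    if lo > 0:
        n = max(2, int(math.ceil(lo / 1.0)) + 1)
        segments.append(np.linspace(0.0, lo, n)[:-1])
    n_throat = max(2, int(math.ceil(geom.throat_length_Ls / (geom.throat_length_Ls / 20.0))) + 1)
    segments.append(np.linspace(lo, hi, n_throat)[:-1])
    n = max(2, int(math.ceil((geom.total_length_L - hi) / 1.0)) + 1)
    segments.append(np.linspace(hi, geom.total_length_L, n))
    return np.concatenate(segments)


def generate_surface(geom: StenosisGeometry) -> trimesh.Trimesh:
    """Triangulated surface of revolution of the lumen wall (mm units).

    Open tube: 2 * n_circumferential * (n_axial - 1) triangles; fan caps add
    n_circumferential triangles each.  Normals point outward (away from the
    axis); the mesh is watertight up to the open rims (or fully watertight
    when capped).
    """
    z = axial_stations(geom)
    nz = z.size
    nt = geom.n_circumferential
    if nz < 2:
        raise ValueError("degenerate axial resolution")
    radii = np.asarray(radius_profile(z, geom), dtype=float)
    theta = np.linspace(0.0, 2.0 * math.pi, nt, endpoint=False)
    ct, st = np.cos(theta), np.sin(theta)
    vertices = np.empty((nz * nt, 3))
    for i in range(nz):
        vertices[i * nt : (i + 1) * nt, 0] = radii[i] * ct
        vertices[i * nt : (i + 1) * nt, 1] = radii[i] * st
        vertices[i * nt : (i + 1) * nt, 2] = z[i]
    faces = []
    for i in range(nz - 1):
        for j in range(nt):
            a = i * nt + j
            b = i * nt + (j + 1) % nt
            c = (i + 1) * nt + j
            d = (i + 1) * nt + (j + 1) % nt
            # outward winding: +z is "up" the tube, CCW seen from outside
            faces.append((a, b, d))
            faces.append((a, d, c))
    vertices_list = [vertices]
    if geom.capped_ends:
        c0 = np.array([[0.0, 0.0, z[0]]])
        c1 = np.array([[0.0, 0.0, z[-1]]])
        i0 = nz * nt
        i1 = nz * nt + 1
        vertices_list += [c0, c1]
        for j in range(nt):
            a = j
            b = (j + 1) % nt
            faces.append((i0, b, a))  # inlet cap faces -z
        base = (nz - 1) * nt
        for j in range(nt):
            a = base + j
            b = base + (j + 1) % nt
            faces.append((i1, a, b))  # outlet cap faces +z
    mesh = trimesh.Trimesh(
        vertices=np.vstack(vertices_list),
        faces=np.asarray(faces, dtype=np.int64),
        process=False,
    )
    return mesh


def write_stl(
    mesh: trimesh.Trimesh,
    path: str | Path,
    mode: str = "binary",
    scale: float = 1.0,
) -> Path:
    """Write a mesh to STL (``binary`` or ``ascii``), optionally scaled.

    ``scale=0.001`` converts the native millimetre coordinates to metres.
    """
    if len(mesh.faces) == 0:
        raise ValueError("refusing to write an empty mesh")
    if mode not in ("binary", "ascii"):
        raise ValueError(f"mode must be 'binary' or 'ascii', got {mode!r}")
    out = mesh.copy()
    if scale != 1.0:
        out.apply_scale(scale)
    path = Path(path)
    try:
        data = trimesh.exchange.stl.export_stl_ascii(out) if mode == "ascii" else trimesh.exchange.stl.export_stl(out)
        if isinstance(data, str):
            path.write_text(data)
        else:
            path.write_bytes(data)
    except OSError as exc:
        raise OSError(f"failed writing STL to {path}: {exc}") from exc
    return path


def read_stl(path: str | Path) -> trimesh.Trimesh:
    """Read an STL file back into a mesh (no vertex merging or processing)."""
    return trimesh.load(str(path), file_type="stl", process=False)
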