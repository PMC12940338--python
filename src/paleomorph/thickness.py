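"""Shape-diameter-function (SDF) thickness mapping of enamel meshes.

The SDF estimates the local diameter of a solid at each surface point by
casting rays inside a cone centered on the point's inward normal and
measuring how far each ray travels before exiting the solid.  Rays far
from the per-vertex median length are discarded as outliers and the rest
are averaged with weights that fall off with the ray's angle to the
normal.  The resulting per-vertex thickness field is rendered as a
topographic map on a dark-blue-to-red chromatic scale.

Cone directions are a deterministic low-discrepancy spiral (the seed only
rotates the spiral), and the per-vertex ray frame is built from the mesh's
own edges, so values are reproducible and invariant under rigid motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from matplotlib import colormaps

__all__ = ["SDFParams", "VertexQuality", "sdf_thickness", "colorize", "save_quality_ply"]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class SDFParams:
    """SDF sampling parameters.

    cone_half_angle: cone aperture around the inward normal, degrees.
    n_rays: rays per vertex.
    outlier_sd: rays deviating from the per-vertex median by more than
        this many standard deviations are discarded.
    seed: rotates the ray spiral (reproducibility contract).
    """

    cone_half_angle: float = 60.0
    n_rays: int = 30
    outlier_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cone_half_angle < 90:
            raise ValueError("cone_half_angle must lie in (0, 90) degrees")
        if self.n_rays < 1:
            raise ValueError("n_rays must be >= 1")
        if self.outlier_sd <= 0:
            raise ValueError("outlier_sd must be positive")


@dataclass
class VertexQuality:
    """Per-vertex thickness values (mm) and their display colors."""

    values: np.ndarray
    colors: np.ndarray | None = None
    fallback: np.ndarray | None = None


def _cone_angles(p: SDFParams) -> tuple[np.ndarray, np.ndarray]:
    """Polar/azimuthal angles of the low-discrepancy spiral in the cone."""
    i = np.arange(p.n_rays)
    frac = (i + 0.5) / p.n_rays
    cos_alpha = np.cos(np.radians(p.cone_half_angle))
    theta = np.arccos(1.0 - frac * (1.0 - cos_alpha))  # uniform in solid angle
    rng = np.random.default_rng(p.seed)
    phi = i * _GOLDEN_ANGLE + rng.uniform(0.0, 2.0 * np.pi)
    return theta, phi


def _vertex_frames(mesh: trimesh.Trimesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inward normal and two tangents per vertex.

    The first tangent comes from the lowest-index neighbor edge projected
    into the tangent plane — an intrinsic construction that co-rotates
    with the mesh, making values rigid-motion invariant.
    """
    inward = -np.asarray(mesh.vertex_normals, dtype=float)
    n_vert = len(mesh.vertices)
    t1 = np.zeros((n_vert, 3))
    for vi in range(n_vert):
        n = inward[vi]
        for nb in sorted(mesh.vertex_neighbors[vi]):
            e = mesh.vertices[nb] - mesh.vertices[vi]
            proj = e - np.dot(e, n) * n
            norm = np.linalg.norm(proj)
            if norm > 1e-12:
                t1[vi] = proj / norm
                break
        else:  # isolated or pathological vertex: arbitrary but deterministic
            h = np.zeros(3)
            h[int(np.argmin(np.abs(n)))] = 1.0
            proj = h - np.dot(h, n) * n
            t1[vi] = proj / np.linalg.norm(proj)
    t2 = np.cross(inward, t1)
    return inward, t1, t2


def _first_hit_distances(
    triangles: np.ndarray,
    origins: np.ndarray,
    directions: np.ndarray,
    chunk: int = 256,
) -> np.ndarray:
    """Distance to the nearest forward ray-triangle intersection.

    Vectorized Moeller-Trumbore over all triangles, chunked over rays;
    rays that hit nothing get NaN.  Intersections closer than ~0 along
    the ray are ignored (origins are already offset off the surface).
    """
    v0 = triangles[:, 0]
    e1 = triangles[:, 1] - v0
    e2 = triangles[:, 2] - v0
    out = np.full(len(origins), np.nan)
    for lo in range(0, len(origins), chunk):
        o = origins[lo : lo + chunk]  # (r, 3)
        d = directions[lo : lo + chunk]
        p = np.cross(d[:, None, :], e2[None, :, :])  # (r, f, 3)
        det = np.einsum("fk,rfk->rf", e1, p)
        ok = np.abs(det) > 1e-12
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        s = o[:, None, :] - v0[None, :, :]
        u = np.einsum("rfk,rfk->rf", s, p) * inv
        q = np.cross(s, e1[None, :, :])
        v = np.einsum("rk,rfk->rf", d, q) * inv
        t = np.einsum("fk,rfk->rf", e2, q) * inv
        hit = ok & (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1 + 1e-12) & (t > 1e-12)
        t = np.where(hit, t, np.inf)
        tmin = t.min(axis=1)
        found = np.isfinite(tmin)
        out[lo : lo + chunk][found] = tmin[found]
    return out


def sdf_thickness(
    mesh: trimesh.Trimesh, params: SDFParams = SDFParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex local diameter of a watertight solid, in mesh units.

    Returns ``(values, fallback)`` where ``fallback[i]`` marks vertices
    whose cone produced no valid ray and whose value is the straight
    inward-normal ray length instead.
    """
    if not mesh.is_watertight:
        raise ValueError("SDF requires a watertight mesh")
    n_vert = len(mesh.vertices)
    theta, phi = _cone_angles(params)
    inward, t1, t2 = _vertex_frames(mesh)

    # directions[v, r] = cos(theta) n + sin(theta) (cos(phi) t1 + sin(phi) t2)
    ct, st = np.cos(theta), np.sin(theta)
    cp, sp = np.cos(phi), np.sin(phi)
    dirs = (
        ct[None, :, None] * inward[:, None, :]
        + (st * cp)[None, :, None] * t1[:, None, :]
        + (st * sp)[None, :, None] * t2[:, None, :]
    ).reshape(-1, 3)
    eps = 1e-6 * float(np.linalg.norm(mesh.bounds[1] - mesh.bounds[0]))
    origins = np.repeat(mesh.vertices, params.n_rays, axis=0) + eps * np.repeat(
        inward, params.n_rays, axis=0
    )

    triangles = mesh.triangles
    t_hit = _first_hit_distances(triangles, origins, dirs)
    lengths = (t_hit + eps).reshape(n_vert, params.n_rays)
    angles = np.broadcast_to(theta, (n_vert, params.n_rays))
    weights = 1.0 / (1.0 + angles)

    values = np.full(n_vert, np.nan)
    fallback = np.zeros(n_vert, dtype=bool)
    for vi in range(n_vert):
        li = lengths[vi]
        ok = np.isfinite(li)
        if ok.any():
            med = np.median(li[ok])
            sd = np.std(li[ok])
            keep = ok & (np.abs(li - med) <= params.outlier_sd * sd + 1e-12)
            w = weights[vi][keep]
            values[vi] = float(np.sum(w * li[keep]) / np.sum(w))
        else:
            fallback[vi] = True
    if fallback.any():
        idx = np.nonzero(fallback)[0]
        t_norm = _first_hit_distances(
            triangles, mesh.vertices[idx] + eps * inward[idx], inward[idx]
        )
        values[idx] = t_norm + eps
    return values, fallback


def colorize(values: np.ndarray, n_bins: int | None = None) -> np.ndarray:
    """Map thickness values onto the dark-blue-to-red chromatic scale.

    An affine map takes [min, max] onto the scale; a constant field maps
    to the scale midpoint.  ``n_bins`` quantizes the scale if given.
    Returns uint8 RGB per vertex.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if not finite.any():
        raise ValueError("no finite thickness values to colorize")
    vmin = float(values[finite].min())
    vmax = float(values[finite].max())
    if vmax > vmin:
        norm = (values - vmin) / (vmax - vmin)
    else:
        norm = np.full_like(values, 0.5)
    norm = np.where(finite, norm, 0.5)
    if n_bins is not None:
        if n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        norm = np.floor(norm * n_bins).clip(0, n_bins - 1) / (n_bins - 1)
    rgba = colormaps["jet"](norm)
    return (rgba[:, :3] * 255).astype(np.uint8)


def save_quality_ply(
    mesh: trimesh.Trimesh, quality: VertexQuality, path: str
) -> None:
    """Write the mesh with per-vertex colors (and values) to a PLY file."""
    out = mesh.copy()
    colors = quality.colors if quality.colors is not None else colorize(quality.values)
    out.visual.vertex_colors = colors
    out.export(path)
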