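"""Synthetic nested source-space geometry for MEG generative models.

This module builds the two anatomical ingredients of the generative models
compared throughout the package: a one-hemisphere cortex-like shell and a
curved, capsule-shaped ("banana") hippocampus-like tube nested inside it.
Real cortical and hippocampal surfaces are FreeSurfer products of a subject
MRI; here both are parametric stand-ins with matched vertex spacing, outward
unit normals (the assumed direction of net pyramidal-cell current flow) and
configurable scale.  The paper-scale preset uses 10595 cortical and 162
hippocampal vertices at ~3.7 mm spacing; the default desk scale is smaller.

Coordinates are a right-handed head frame in millimetres, origin near the
head centre, with +z towards the vertex of the head.  Vertex indices are
0-based everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import ConvexHull, cKDTree

__all__ = [
    "SurfaceMesh",
    "SourceSpace",
    "PatchWeights",
    "GeometryError",
    "generate_cortex_mesh",
    "generate_hippocampus_mesh",
    "match_mesh_spacing",
    "patch_weights",
    "make_source_space",
    "transform_hippocampus",
    "shift_battery",
    "nearest_cortical_neighbours",
]

CORTICAL = "cortical"
HIPPOCAMPAL = "hippocampal"

#: FWHM of a Gaussian = sigma * 2*sqrt(2*ln 2)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


class GeometryError(ValueError):
    """Raised when requested geometry is infeasible or inconsistent."""


# ---------------------------------------------------------------------------
# core types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangulated surface with per-vertex outward unit normals.

    Parameters
    ----------
    vertices : (n, 3) float array, positions in mm (head coordinates).
    faces : (m, 3) int array, 0-based triangle vertex indices.
    normals : (n, 3) float array, unit outward normals.
    structure_label : ``"cortical"`` or ``"hippocampal"``.
    """

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray
    structure_label: str

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (e, 2) index array."""
        f = self.faces
        e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def edge_lengths(self) -> np.ndarray:
        e = self.edges()
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)

    def mean_edge_length(self) -> float:
        return float(self.edge_lengths().mean())

    def adjacency(self):
        """Sparse symmetric vertex adjacency weighted by Euclidean edge length."""
        e = self.edges()
        w = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
        n = self.n_vertices
        g = coo_matrix(
            (np.concatenate([w, w]), (np.concatenate([e[:, 0], e[:, 1]]),
                                      np.concatenate([e[:, 1], e[:, 0]]))),
            shape=(n, n),
        )
        return g.tocsr()

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def is_connected(self) -> bool:
        n_comp, _ = connected_components(self.adjacency(), directed=False)
        return n_comp == 1

    def validate(self, target_spacing_mm: float | None = None) -> None:
        """Audit structural invariants; raise :class:`GeometryError` on failure."""
        v, f, n = self.vertices, self.faces, self.normals
        if v.ndim != 2 or v.shape[1] != 3 or n.shape != v.shape:
            raise GeometryError("vertices/normals must be (n, 3) arrays")
        if f.min() < 0 or f.max() >= len(v):
            raise GeometryError("face index out of range")
        norms = np.linalg.norm(n, axis=1)
        if np.abs(norms - 1.0).max() >= 1e-9:
            raise GeometryError("normals are not unit length")
        if not self.is_connected():
            raise GeometryError("mesh graph is not connected")
        if target_spacing_mm is not None:
            mean = self.mean_edge_length()
            if not (0.85 * target_spacing_mm <= mean <= 1.15 * target_spacing_mm):
                raise GeometryError(
                    f"mean edge length {mean:.3f} mm outside +/-15% of "
                    f"target {target_spacing_mm:.3f} mm"
                )


@dataclass(frozen=True)
class SourceSpace:
    """Ordered collection of surface meshes forming one anatomical model.

    ``anatomy_kind`` is ``"cortical"`` (cortex only) or ``"combined"``
    (the identical cortical mesh plus one hippocampal mesh appended).
    Vertices of member meshes are concatenated; ``vertex_offset[i]`` is the
    start index of mesh ``i`` in the concatenated ordering.
    """

    meshes: tuple[SurfaceMesh, ...]
    vertex_offset: tuple[int, ...]
    anatomy_kind: str

    @property
    def n_vertices(self) -> int:
        return sum(m.n_vertices for m in self.meshes)

    @property
    def vertices(self) -> np.ndarray:
        return np.vstack([m.vertices for m in self.meshes])

    @property
    def normals(self) -> np.ndarray:
        return np.vstack([m.normals for m in self.meshes])

    @property
    def cortical_mesh(self) -> SurfaceMesh:
        return self.meshes[0]

    @property
    def hippocampal_mesh(self) -> SurfaceMesh:
        if self.anatomy_kind != "combined":
            raise ValueError("cortical-kind source space has no hippocampal mesh")
        return self.meshes[1]

    def structure_of(self, index):
        """Structure label(s) of concatenated vertex index/indices."""
        idx = np.atleast_1d(np.asarray(index))
        out = np.empty(idx.shape, dtype=object)
        for mesh, off in zip(self.meshes, self.vertex_offset):
            sel = (idx >= off) & (idx < off + mesh.n_vertices)
            out[sel] = mesh.structure_label
        if np.isscalar(index) or np.asarray(index).ndim == 0:
            return out.item()
        return out

    def global_index(self, mesh_i: int, local_index):
        return self.vertex_offset[mesh_i] + np.asarray(local_index)


@dataclass(frozen=True)
class PatchWeights:
    """Gaussian patch profile over graph-geodesic distance from a seed vertex."""

    seed_vertex: int
    weights: np.ndarray
    fwhm_mm: float


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _vertex_normals(vertices: np.ndarray, faces: np.ndarray,
                    outward_from: np.ndarray | None = None,
                    fix_winding: bool = False) -> np.ndarray:
    tm = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    if fix_winding:
        # closed surfaces: make winding consistent and outward (volume > 0)
        trimesh.repair.fix_normals(tm)
    normals = np.array(tm.vertex_normals, dtype=float)
    if outward_from is not None:
        # flip any normal pointing towards the given interior reference
        outward = vertices - outward_from
        flip = np.einsum("ij,ij->i", normals, outward) < 0
        normals[flip] *= -1.0
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return normals


def _fibonacci_cap(n: int, z_min: float, rng_offset: float = 0.0) -> np.ndarray:
    """n near-uniform points on the unit-sphere cap z in (z_min, 1]."""
    i = np.arange(n)
    z = 1.0 - (1.0 - z_min) * (i + 0.5) / n
    theta = i * _GOLDEN_ANGLE + rng_offset
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


# ---------------------------------------------------------------------------
# cortex generation
# ---------------------------------------------------------------------------


def generate_cortex_mesh(n_target_vertices: int, spacing_mm: float,
                         seed: int = 0, *,
                         perturbation_amplitude: float = 0.04) -> SurfaceMesh:
    """Generate a cortex-like hemispheric shell with perturbed radius.

    Vertices are a Fibonacci lattice on a hemisphere, triangulated by convex
    hull, uniformly scaled so the mean edge length equals ``spacing_mm``,
    then given a smooth low-order radial perturbation (amplitude a few % of
    the radius) so that vertex normals vary realistically rather than being
    exactly radial.  Deterministic given ``seed``; exactly
    ``n_target_vertices`` vertices.
    """
    if n_target_vertices < 100 or spacing_mm <= 0:
        raise GeometryError(
            f"infeasible cortex parameters: n_target_vertices={n_target_vertices} "
            f"(need >= 100), spacing_mm={spacing_mm} (need > 0)"
        )
    n = int(n_target_vertices)
    rng = np.random.default_rng(seed)

    pts = _fibonacci_cap(n, z_min=0.0)
    # close the body with a ghost apex so the hull's bottom disc triangulates
    # to the ghost only; drop those faces afterwards -> open hemispheric shell
    ghost = np.array([[0.0, 0.0, -1.0]])
    hull = ConvexHull(np.vstack([pts, ghost]))
    faces = hull.simplices
    faces = faces[(faces < n).all(axis=1)]

    # uniform scale to the requested spacing
    mesh0 = SurfaceMesh(pts, faces, np.zeros_like(pts), CORTICAL)
    scale = spacing_mm / mesh0.mean_edge_length()
    vertices = pts * scale

    # smooth radial perturbation: a few random low-order directional waves
    unit = pts  # already unit vectors
    bump = np.zeros(n)
    for _ in range(6):
        k = rng.uniform(4.0, 9.0)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        bump += rng.normal() * np.sin(k * unit @ d + phase)
    bump *= perturbation_amplitude / max(np.abs(bump).max(), 1e-12)
    vertices = vertices * (1.0 + bump)[:, None]

    normals = _vertex_normals(vertices, faces, outward_from=np.zeros(3))
    mesh = SurfaceMesh(vertices, faces, normals, CORTICAL)
    mesh.validate(target_spacing_mm=spacing_mm)
    return mesh


# ---------------------------------------------------------------------------
# hippocampus generation
# ---------------------------------------------------------------------------


def _capsule_points(n: int, body_len: float, radius: float) -> np.ndarray:
    """Area-uniform points on a straight capsule (axis along z, centred)."""
    a, h = radius, body_len
    area_cap = 2.0 * np.pi * a * a         # each hemispherical cap
    area_body = 2.0 * np.pi * a * h
    total = 2.0 * area_cap + area_body
    i = np.arange(n)
    s = (i + 0.5) / n * total
    theta = i * _GOLDEN_ANGLE
    z = np.empty(n)
    rho = np.empty(n)
    # bottom cap: pole at z = -h/2 - a
    m = s < area_cap
    xi = s[m] / (2.0 * np.pi * a)          # height above the pole, in [0, a]
    z[m] = -h / 2.0 - (a - xi)
    rho[m] = np.sqrt(np.clip(a * a - (a - xi) ** 2, 0.0, None))
    # body
    m = (s >= area_cap) & (s < area_cap + area_body)
    z[m] = -h / 2.0 + (s[m] - area_cap) / (2.0 * np.pi * a)
    rho[m] = a
    # top cap
    m = s >= area_cap + area_body
    xi = (s[m] - area_cap - area_body) / (2.0 * np.pi * a)
    z[m] = h / 2.0 + xi
    rho[m] = np.sqrt(np.clip(a * a - xi * xi, 0.0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def generate_hippocampus_mesh(n_target_vertices: int, spacing_mm: float,
                              centroid_depth_mm: float = 28.0, seed: int = 0, *,
                              axis_length_mm: float = 50.0,
                              bend_radius_mm: float | None = 45.0,
                              cortex_mesh: SurfaceMesh | None = None,
                              cortex_radius_mm: float = 60.0,
                              direction=(0.55, -0.55, 0.63),
                              allowed_bulge_mm: float = 0.0) -> SurfaceMesh:
    """Generate a hippocampus-like curved capsule nested inside the cortex.

    The surface is a capsule (cylinder with hemispherical caps) whose tube
    radius is solved from the requested vertex count and spacing, meshed with
    an area-uniform Fibonacci lattice + convex-hull triangulation, optionally
    bent around a circular arc of radius ``bend_radius_mm`` (``None`` keeps
    it straight), and placed with its centroid ``centroid_depth_mm`` below
    the cortical shell along ``direction``.

    ``axis_length_mm`` is the tip-to-tip geodesic length of the surface
    meridian (cap arcs included), matching the ~5 cm extent of the adult
    hippocampus at the default.
    """
    if n_target_vertices < 20 or spacing_mm <= 0:
        raise GeometryError(
            f"infeasible hippocampus parameters: n={n_target_vertices}, "
            f"spacing={spacing_mm}"
        )
    n = int(n_target_vertices)
    L = axis_length_mm

    def _solve_capsule(area):
        # capsule with meridian length L = body + pi*a:
        #   A = 2*pi*a*(L - pi*a) + 4*pi*a^2
        coef = 4.0 * np.pi - 2.0 * np.pi**2
        disc = (2.0 * np.pi * L) ** 2 + 4.0 * coef * area
        if disc <= 0:
            raise GeometryError(
                f"no capsule radius fits n={n}, spacing={spacing_mm} mm, "
                f"axis_length={L} mm"
            )
        a = (2.0 * np.pi * L - np.sqrt(disc)) / (-2.0 * coef)
        body = L - np.pi * a
        if a <= 0 or body <= 0:
            raise GeometryError(
                f"infeasible capsule: radius={a:.2f} mm, body={body:.2f} mm "
                f"from n={n}, spacing={spacing_mm}, axis_length={L}"
            )
        return a, body

    # triangulate in a sphere parameter domain: the capsule lattice shares
    # its (area-fraction, spiral-angle) parametrization with a Fibonacci
    # sphere, whose convex hull gives well-shaped neighbour triangles --
    # hulling the elongated capsule directly yields skinny faces
    i = np.arange(n)
    z_s = 1.0 - 2.0 * (i + 0.5) / n
    th = i * _GOLDEN_ANGLE
    rho_s = np.sqrt(np.clip(1.0 - z_s**2, 0.0, None))
    sphere = np.column_stack([rho_s * np.cos(th), rho_s * np.sin(th), z_s])
    faces = ConvexHull(sphere).simplices

    # the discrete triangulation's mean edge runs a few % above the
    # equilateral-lattice estimate; one corrective pass re-solves the tube
    # radius at fixed meridian length so spacing and axis length both hold
    area = np.sqrt(3.0) / 2.0 * n * spacing_mm**2
    a, body = _solve_capsule(area)
    pts = _capsule_points(n, body, a)
    mesh0 = SurfaceMesh(pts, faces, np.zeros_like(pts), HIPPOCAMPAL)
    bias = mesh0.mean_edge_length() / spacing_mm
    a, body = _solve_capsule(area / bias**2)
    pts = _capsule_points(n, body, a)
    # final uniform rescale pins the mean edge exactly; the corrective pass
    # above keeps the residual scale (and hence axis-length error) small
    mesh1 = SurfaceMesh(pts, faces, np.zeros_like(pts), HIPPOCAMPAL)
    scale = spacing_mm / mesh1.mean_edge_length()
    pts = pts * scale
    a, body = a * scale, body * scale

    if bend_radius_mm is not None:
        if bend_radius_mm <= 2.0 * a:
            raise GeometryError(
                f"bend radius {bend_radius_mm} mm too tight for tube radius "
                f"{a:.2f} mm"
            )
        beta = pts[:, 2] / bend_radius_mm
        r_eff = bend_radius_mm + pts[:, 1]
        pts = np.column_stack([
            pts[:, 0],
            r_eff * np.cos(beta) - bend_radius_mm,
            r_eff * np.sin(beta),
        ])

    # orient the long axis roughly anterior-posterior and place the centroid
    rng = np.random.default_rng(seed)
    roll = rng.uniform(0.0, 2.0 * np.pi)  # random roll about the long axis
    cr, sr = np.cos(roll), np.sin(roll)
    R_roll = np.array([[cr, -sr, 0.0], [sr, cr, 0.0], [0.0, 0.0, 1.0]])
    # long axis (local z) -> y axis of the head frame
    R_axis = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0], [0.0, -1.0, 0.0]])
    pts = pts @ R_roll.T @ R_axis.T

    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    if cortex_mesh is not None:
        shell_radius = float(np.linalg.norm(cortex_mesh.vertices, axis=1).mean())
    else:
        shell_radius = float(cortex_radius_mm)
    centroid_target = d * (shell_radius - centroid_depth_mm)
    pts = pts - pts.mean(axis=0) + centroid_target

    if cortex_mesh is not None:
        limit = np.linalg.norm(cortex_mesh.vertices, axis=1).min() + allowed_bulge_mm
        outside = np.linalg.norm(pts, axis=1) > limit
        if outside.any():
            raise GeometryError(
                f"hippocampal tube intersects the cortical shell: "
                f"{int(outside.sum())} vertices beyond radius {limit:.1f} mm "
                f"(allowed bulge {allowed_bulge_mm} mm)"
            )

    normals = _vertex_normals(pts, faces, fix_winding=True)
    mesh = SurfaceMesh(pts, faces, normals, HIPPOCAMPAL)
    mesh.validate(target_spacing_mm=spacing_mm)
    return mesh


# ---------------------------------------------------------------------------
# spacing matching (smooth + decimate)
# ---------------------------------------------------------------------------


def match_mesh_spacing(mesh: SurfaceMesh, target_spacing_mm: float,
                       tolerance: float = 0.05) -> SurfaceMesh:
    """Decimate (edge-collapse) + lightly smooth a mesh to a target spacing.

    Mirrors the preprocessing applied to a dense segmented surface so that
    mean vertex-vertex distances match a paired mesh.  Returns the input
    unchanged if its mean edge length is already within ``tolerance`` of the
    target.  Requires the input to be denser (smaller spacing) than the
    target otherwise.
    """
    mean0 = mesh.mean_edge_length()
    if abs(mean0 - target_spacing_mm) <= tolerance * target_spacing_mm:
        return mesh
    if mean0 > target_spacing_mm:
        raise GeometryError(
            f"mesh spacing {mean0:.2f} mm is already coarser than target "
            f"{target_spacing_mm:.2f} mm"
        )

    vertices = mesh.vertices.copy()
    faces = mesh.faces.copy()

    def _mean_edge(v, f):
        e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e.sort(axis=1)
        e = np.unique(e, axis=0)
        return e, float(np.linalg.norm(v[e[:, 0]] - v[e[:, 1]], axis=1).mean())

    while True:
        edges, mean = _mean_edge(vertices, faces)
        if mean >= (1.0 - tolerance) * target_spacing_mm:
            break
        lengths = np.linalg.norm(vertices[edges[:, 0]] - vertices[edges[:, 1]], axis=1)
        order = np.argsort(lengths)
        # collapse an independent set of the shortest edges (no shared vertex)
        n_batch = max(1, int(0.04 * len(order)))
        used = np.zeros(len(vertices), dtype=bool)
        mapping = np.arange(len(vertices))
        collapsed = 0
        for ei in order:
            u, v = edges[ei]
            if used[u] or used[v]:
                continue
            vertices[u] = 0.5 * (vertices[u] + vertices[v])
            mapping[v] = u
            used[u] = used[v] = True
            collapsed += 1
            if collapsed >= n_batch:
                break
        if collapsed == 0:
            raise GeometryError(
                f"decimation stalled before reaching target spacing "
                f"{target_spacing_mm} mm (mesh extent may not support it)"
            )
        faces = mapping[faces]
        keep = (
            (faces[:, 0] != faces[:, 1])
            & (faces[:, 1] != faces[:, 2])
            & (faces[:, 0] != faces[:, 2])
        )
        faces = faces[keep]
        # drop unreferenced vertices, reindex
        ref = np.unique(faces)
        remap = -np.ones(len(vertices), dtype=int)
        remap[ref] = np.arange(len(ref))
        vertices = vertices[ref]
        faces = remap[faces]

    # light Taubin smoothing (shrink-compensated), then a uniform rescale
    tm = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    trimesh.smoothing.filter_taubin(tm, lamb=0.5, nu=0.53, iterations=5)
    vertices = np.array(tm.vertices, dtype=float)
    _, mean = _mean_edge(vertices, faces)
    if abs(mean - target_spacing_mm) > tolerance * target_spacing_mm:
        centre = vertices.mean(axis=0)
        vertices = centre + (vertices - centre) * (target_spacing_mm / mean)

    normals = _vertex_normals(vertices, faces, outward_from=vertices.mean(axis=0))
    out = SurfaceMesh(vertices, faces, normals, mesh.structure_label)
    if not out.is_connected():
        raise GeometryError("decimation broke mesh connectivity")
    return out


# ---------------------------------------------------------------------------
# patches
# ---------------------------------------------------------------------------


def geodesic_distances(mesh: SurfaceMesh, seed_vertex: int) -> np.ndarray:
    """Graph-geodesic distance (mm) from a seed to every vertex."""
    return dijkstra(mesh.adjacency(), directed=False, indices=seed_vertex)


def patch_weights(mesh: SurfaceMesh, seed_vertex: int, fwhm_mm: float,
                  truncate: float = 1e-3) -> PatchWeights:
    """Gaussian patch profile w(v) = exp(-d(v)^2 / (2 sigma^2)).

    ``d`` is the graph-geodesic distance from the seed along mesh edges and
    ``sigma = fwhm_mm / sqrt(8 ln 2)``.  Weights below ``truncate`` times the
    peak are set exactly to zero, keeping patch covariance components sparse.
    """
    if not (0 <= seed_vertex < mesh.n_vertices):
        raise IndexError(f"seed vertex {seed_vertex} out of range")
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    d = geodesic_distances(mesh, seed_vertex)
    unreachable = ~np.isfinite(d)
    if unreachable.any():
        warnings.warn(
            "mesh is disconnected; patch weights confined to the seed component",
            RuntimeWarning,
            stacklevel=2,
        )
        d = np.where(unreachable, np.inf, d)
    sigma = fwhm_mm * FWHM_TO_SIGMA
    w = np.exp(-(d**2) / (2.0 * sigma**2))
    w[w < truncate] = 0.0
    return PatchWeights(seed_vertex=int(seed_vertex), weights=w, fwhm_mm=float(fwhm_mm))


# ---------------------------------------------------------------------------
# source spaces and control transforms
# ---------------------------------------------------------------------------


def make_source_space(cortex: SurfaceMesh,
                      hippocampus: SurfaceMesh | None = None) -> SourceSpace:
    """Assemble a cortical or combined source space from component meshes."""
    if cortex.structure_label != CORTICAL:
        raise ValueError("first mesh must be cortical")
    if hippocampus is None:
        return SourceSpace(meshes=(cortex,), vertex_offset=(0,),
                           anatomy_kind="cortical")
    if hippocampus.structure_label != HIPPOCAMPAL:
        raise ValueError("second mesh must be hippocampal")
    return SourceSpace(
        meshes=(cortex, hippocampus),
        vertex_offset=(0, cortex.n_vertices),
        anatomy_kind="combined",
    )


def _rotation_matrix(axis, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.deg2rad(angle_deg)
    c, s = np.cos(t), np.sin(t)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(axis, axis)


def transform_hippocampus(space: SourceSpace, shift_mm=None,
                          rotation_deg: float | None = None,
                          rotation_axis=(0.0, 0.0, 1.0)) -> SourceSpace:
    """Rigidly displace or rotate the hippocampal mesh of a combined space.

    Control manipulation for anatomical-specificity analyses: the cortical
    mesh is untouched (the returned space shares the identical object) and
    the hippocampal mesh is shifted by ``shift_mm`` and/or rotated by
    ``rotation_deg`` about ``rotation_axis`` through the hippocampal
    centroid.  The default axis is the head-frame z (axial-plane rotation).
    """
    if space.anatomy_kind != "combined":
        raise ValueError("transform_hippocampus requires a combined source space")
    hip = space.hippocampal_mesh
    v = hip.vertices.copy()
    n = hip.normals.copy()
    if rotation_deg is not None and rotation_deg != 0.0:
        R = _rotation_matrix(rotation_axis, rotation_deg)
        c = v.mean(axis=0)
        v = (v - c) @ R.T + c
        n = n @ R.T
    if shift_mm is not None:
        v = v + np.asarray(shift_mm, dtype=float)
    new_hip = replace(hip, vertices=v, normals=n)
    return SourceSpace(
        meshes=(space.cortical_mesh, new_hip),
        vertex_offset=space.vertex_offset,
        anatomy_kind="combined",
    )


def shift_battery(magnitudes_mm=(5.0, 10.0, 15.0, 20.0)) -> list[np.ndarray]:
    """The 24 rigid hippocampal shifts: 4 magnitudes x 3 axes x 2 signs."""
    shifts = []
    for mag in magnitudes_mm:
        for axis in range(3):
            for sign in (+1.0, -1.0):
                s = np.zeros(3)
                s[axis] = sign * mag
                shifts.append(s)
    return shifts


def nearest_cortical_neighbours(space: SourceSpace,
                                hippocampal_vertices=None):
    """Euclidean-nearest cortical vertex for each given hippocampal vertex.

    Returns a list of ``(hippocampal_local_index, cortical_index,
    distance_mm)`` tuples.  Used to place the closest-cortical-neighbour
    control simulations.
    """
    if space.anatomy_kind != "combined":
        raise ValueError("requires a combined source space")
    hip = space.hippocampal_mesh
    if hippocampal_vertices is None:
        hippocampal_vertices = np.arange(hip.n_vertices)
    hippocampal_vertices = np.asarray(hippocampal_vertices, dtype=int)
    tree = cKDTree(space.cortical_mesh.vertices)
    dist, idx = tree.query(hip.vertices[hippocampal_vertices])
    return [
        (int(h), int(c), float(d))
        for h, c, d in zip(hippocampal_vertices, idx, dist)
    ]
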