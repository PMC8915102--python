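"""Lesion shape markers from a spherical-harmonics surface expansion.

The lesion surface is meshed from its binary mask, relaxed onto the unit
sphere by an attraction-repulsion scheme (attraction centers each node among
its mesh neighbors, repulsion keeps the spherical mesh from collapsing,
projection restores unit norm), and the per-vertex radial distance from an
interior origin is expanded in the real spherical-harmonic basis.  The shape
markers are the root-mean-square radial reconstruction errors of the
truncated series at orders 1..85: smooth (benign-like) surfaces are rebuilt
accurately at low order, while spiky (malignant-like) surfaces need many
harmonics, so their error curve decays slowly.  Markers are normalized by
the mean radius by default, making them scale-invariant descriptors of
complexity rather than size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .features import FeatureVector
from .spharm import n_sh_coefficients, real_sh_degree_block

__all__ = [
    "SurfaceMesh",
    "ARConfig",
    "SphericalMapping",
    "SHModel",
    "MeshTopologyError",
    "SphericalMappingError",
    "mesh_from_mask",
    "choose_origin",
    "attraction_repulsion",
    "fit_sh",
    "shape_feature_vector",
    "shape_features_from_mask",
]


class MeshTopologyError(ValueError):
    """Mask or mesh violates the closed genus-0 requirement."""


class SphericalMappingError(RuntimeError):
    """Attraction-repulsion terminated with an invalid (folded) mapping."""


@dataclass
class SurfaceMesh:
    """Closed genus-0 triangulated surface with per-vertex neighbor sets."""

    vertices: np.ndarray  # (I, 3) in voxel-physical coordinates
    triangles: np.ndarray  # (F, 3) vertex index triples

    _edges: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def directed_edges(self) -> np.ndarray:
        """(2E, 2) array of directed edges (i, j) — both directions present."""
        if self._edges is None:
            tri = self.triangles
            und = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
            und = np.unique(np.sort(und, axis=1), axis=0)
            self._edges = np.vstack([und, und[:, ::-1]])
        return self._edges

    def neighbor_sets(self) -> list[np.ndarray]:
        edges = self.directed_edges
        order = np.argsort(edges[:, 0], kind="stable")
        src = edges[order, 0]
        dst = edges[order, 1]
        bounds = np.searchsorted(src, np.arange(self.n_vertices + 1))
        return [dst[bounds[i] : bounds[i + 1]] for i in range(self.n_vertices)]

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.triangles, process=False)


def mesh_from_mask(
    lesion_mask: np.ndarray,
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    max_vertices: int = 2000,
    smooth_sigma: float = 0.8,
) -> SurfaceMesh:
    """Closed genus-0 isosurface of a binary mask at level 0.5.

    The mask must be a single 6-connected component.  The binary volume is
    lightly Gaussian-smoothed (``smooth_sigma`` voxels; 0 disables) before
    isosurfacing so the mesh tracks the underlying surface rather than the
    voxel staircase; lesions too small to survive smoothing fall back to the
    raw volume.  If the level-1 mesh exceeds ``max_vertices`` the isosurface
    is re-extracted on progressively coarser marching-cubes grids (larger
    ``step_size``) until it fits — the vertex cap bounds the O(I^2)
    repulsion cost downstream.
    """
    mask = np.asarray(lesion_mask, dtype=bool)
    if not mask.any():
        raise MeshTopologyError("empty lesion mask")
    labels, n_comp = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 1))
    if n_comp > 1:
        raise MeshTopologyError(
            f"lesion mask has {n_comp} connected components; "
            "keep the largest component before meshing"
        )
    # internal cavities would add an inner closed surface; lesions are solids
    mask = ndimage.binary_fill_holes(mask)
    spacing = tuple(float(s) for s in voxel_spacing)
    mesh = None
    for step in range(1, max(mask.shape) + 1):
        pad = step + 1 + int(np.ceil(3 * smooth_sigma))
        padded = np.pad(mask, pad).astype(float)
        if smooth_sigma > 0:
            smoothed = ndimage.gaussian_filter(padded, smooth_sigma)
            if smoothed.max() > 0.5:
                padded = smoothed
        verts, faces, _, _ = measure.marching_cubes(
            padded, level=0.5, spacing=spacing, step_size=step
        )
        verts = verts - pad * np.asarray(spacing)
        tm = trimesh.Trimesh(verts, faces, process=True)
        if len(tm.vertices) <= max_vertices:
            mesh = tm
            break
    if mesh is None:  # pragma: no cover - step_size sweep always terminates
        raise MeshTopologyError("could not coarsen mesh under the vertex cap")
    if not mesh.is_watertight:
        raise MeshTopologyError("isosurface is not closed")
    if mesh.euler_number != 2:
        raise MeshTopologyError(
            f"surface has Euler characteristic {mesh.euler_number}, expected 2 "
            "(genus-0 required for a one-to-one sphere map)"
        )
    trimesh.repair.fix_normals(mesh)
    return SurfaceMesh(
        vertices=np.asarray(mesh.vertices, dtype=float),
        triangles=np.asarray(mesh.faces, dtype=np.int64),
    )


def point_in_mesh(mesh: SurfaceMesh, point: np.ndarray) -> bool:
    """Winding-number containment test for a closed mesh.

    Sums the signed solid angles (van Oosterom-Strackee) of all triangles
    about the point: ~4*pi inside, ~0 outside.  Robust for watertight meshes
    and needs no spatial index.
    """
    p = np.asarray(point, dtype=float)
    a = mesh.vertices[mesh.triangles[:, 0]] - p
    b = mesh.vertices[mesh.triangles[:, 1]] - p
    c = mesh.vertices[mesh.triangles[:, 2]] - p
    la = np.linalg.norm(a, axis=1)
    lb = np.linalg.norm(b, axis=1)
    lc = np.linalg.norm(c, axis=1)
    num = np.einsum("ij,ij->i", a, np.cross(b, c))
    den = (
        la * lb * lc
        + np.einsum("ij,ij->i", a, b) * lc
        + np.einsum("ij,ij->i", b, c) * la
        + np.einsum("ij,ij->i", a, c) * lb
    )
    omega = 2.0 * np.arctan2(num, den)
    return abs(float(omega.sum())) > 2.0 * np.pi  # 4*pi inside, 0 outside


def choose_origin(
    mesh: SurfaceMesh,
    lesion_mask: np.ndarray | None = None,
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Interior origin for the radial surface function.

    Default is the centroid of the mask voxels (volume centroid of the mesh
    when no mask is given), verified strictly inside the surface.  If the
    centroid falls outside (non-star-shaped region), the interior voxel
    maximizing the distance-to-surface transform is used instead.
    """
    spacing = np.asarray(voxel_spacing, dtype=float)
    if lesion_mask is not None:
        idx = np.argwhere(lesion_mask)
        if idx.size == 0:
            raise ValueError("empty lesion mask")
        candidate = idx.mean(axis=0) * spacing
    else:
        candidate = mesh.as_trimesh().center_mass
    if point_in_mesh(mesh, candidate):
        return np.asarray(candidate, dtype=float)
    if lesion_mask is not None:
        edt = ndimage.distance_transform_edt(lesion_mask, sampling=spacing)
        best = np.unravel_index(np.argmax(edt), edt.shape)
        fallback = np.asarray(best, dtype=float) * spacing
        if point_in_mesh(mesh, fallback):
            return fallback
    raise ValueError("no strictly interior origin found for the mesh")


@dataclass(frozen=True)
class ARConfig:
    """Attraction-repulsion parameters.

    ``c_r`` trades accuracy for iterations (smaller = gentler redistribution);
    its useful range is 0.3-0.7.  The attraction strengths keep per-cycle
    steps small so the map stays fold-free.
    """

    c_a1: float = 0.1
    c_a2: float = 0.1
    c_r: float = 0.5
    max_cycles: int = 500
    displacement_tol: float = 1e-4

    def __post_init__(self) -> None:
        if not 0.0 < self.c_r <= 1.0:
            raise ValueError("c_r must lie in (0, 1]")
        if self.c_a1 <= 0 or self.c_a2 <= 0:
            raise ValueError("attraction strengths must be positive")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be at least 1")


@dataclass
class SphericalMapping:
    """One-to-one correspondence between mesh vertices and the unit sphere."""

    unit_coords: np.ndarray  # (I, 3), unit norm
    theta: np.ndarray  # polar angle in [0, pi]
    phi: np.ndarray  # azimuth in [0, 2*pi)
    radii: np.ndarray  # original distance of each vertex from the origin
    n_cycles: int = 0
    final_displacement: float = np.nan

    @property
    def n_vertices(self) -> int:
        return self.unit_coords.shape[0]


def attraction_displacement(
    coords: np.ndarray,
    src: np.ndarray,
    dst: np.ndarray,
    c_a1: float,
    c_a2: float,
) -> np.ndarray:
    """Per-node attraction update over the directed neighbor edges.

    Node i receives ``c_a1 * sum_{j in J_i} (d_ji * ||d_ji||^2 +
    c_a2 * d_ji / ||d_ji||)`` with ``d_ji = C_j - C_i``: a cubic pull toward
    distant neighbors plus a bounded centering term.
    """
    d = coords[dst] - coords[src]
    dist = np.maximum(np.linalg.norm(d, axis=1, keepdims=True), 1e-12)
    contrib = c_a1 * (d * dist**2 + c_a2 * d / dist)
    out = np.zeros_like(coords)
    np.add.at(out, src, contrib)
    return out


def _repulsion_displacement(coords: np.ndarray, c_r: float, chunk: int = 256) -> np.ndarray:
    """-C_R/(2I) * sum_{j != i} d_ji / ||d_ji||^2, computed in row chunks."""
    n = coords.shape[0]
    out = np.empty_like(coords)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        diff = coords[None, :, :] - coords[lo:hi, None, :]  # d_ji = C_j - C_i
        dist2 = np.einsum("ijk,ijk->ij", diff, diff)
        dist2[np.arange(hi - lo), np.arange(lo, hi)] = np.inf
        out[lo:hi] = -(diff / dist2[:, :, None]).sum(axis=1)
    return out * (c_r / (2.0 * n))


def _orientation_signs(coords: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    a = coords[triangles[:, 0]]
    b = coords[triangles[:, 1]]
    c = coords[triangles[:, 2]]
    return np.sign(np.einsum("ij,ij->i", a, np.cross(b, c)))


def attraction_repulsion(
    mesh: SurfaceMesh, origin: np.ndarray, config: ARConfig | None = None
) -> SphericalMapping:
    """Relax the radial projection of the mesh into a near-uniform sphere map.

    Nodes start as unit-norm radial projections of the vertices about
    ``origin``.  Each cycle applies the attraction update over mesh
    neighbors, the all-pairs repulsion with factor ``c_r / (2 I)``, and
    re-projection onto the unit sphere; iteration stops when the mean
    per-vertex displacement drops below ``displacement_tol``.  The final map
    is checked for flipped spherical triangles (a fold would break the
    one-to-one correspondence).
    """
    if config is None:
        config = ARConfig()
    rel = mesh.vertices - np.asarray(origin, dtype=float)
    radii = np.linalg.norm(rel, axis=1)
    if np.any(radii <= 0):
        raise ValueError("a mesh vertex coincides with the origin")
    coords = rel / radii[:, None]

    edges = mesh.directed_edges
    src, dst = edges[:, 0], edges[:, 1]

    def count_flips(c: np.ndarray) -> int:
        signs = _orientation_signs(c, mesh.triangles)
        majority = 1.0 if (signs > 0).sum() >= (signs < 0).sum() else -1.0
        return int((signs * majority < 0).sum())

    n_cycles = 0
    disp = np.nan
    for n_cycles in range(1, config.max_cycles + 1):
        attracted = coords + attraction_displacement(
            coords, src, dst, config.c_a1, config.c_a2
        )
        repelled = attracted + _repulsion_displacement(coords, config.c_r)
        new = repelled / np.linalg.norm(repelled, axis=1, keepdims=True)
        if not np.isfinite(new).all():
            raise SphericalMappingError("non-finite update in attraction-repulsion")
        disp = float(np.linalg.norm(new - coords, axis=1).mean())
        coords = new
        # folds inherited from the voxelized projection are healed by the
        # relaxation itself; do not declare convergence while any remain
        if disp < config.displacement_tol and count_flips(coords) == 0:
            break

    # residual sliver folds (voxelization artifacts at the relaxation's own
    # fixed point) yield to local untangling: move each vertex of a folded
    # triangle to its neighbor centroid and reproject
    if count_flips(coords):
        neighbors = mesh.neighbor_sets()
        for _ in range(100):
            signs = _orientation_signs(coords, mesh.triangles)
            majority = 1.0 if (signs > 0).sum() >= (signs < 0).sum() else -1.0
            bad = np.flatnonzero(signs * majority < 0)
            if bad.size == 0:
                break
            for v in np.unique(mesh.triangles[bad]):
                centroid = coords[neighbors[v]].mean(axis=0)
                coords[v] = centroid / np.linalg.norm(centroid)

    n_flipped = count_flips(coords)
    if n_flipped:
        raise SphericalMappingError(
            f"{n_flipped} flipped spherical triangles at termination; "
            "mapping is not one-to-one (try smaller attraction steps)"
        )

    theta = np.arccos(np.clip(coords[:, 2], -1.0, 1.0))
    phi = np.mod(np.arctan2(coords[:, 1], coords[:, 0]), 2.0 * np.pi)
    return SphericalMapping(
        unit_coords=coords,
        theta=theta,
        phi=phi,
        radii=radii,
        n_cycles=n_cycles,
        final_displacement=disp,
    )


@dataclass
class SHModel:
    """Least-squares SH expansion of the radial surface function.

    ``order_errors[k]`` is the RMS radial reconstruction error of the series
    truncated at degree k (nested fits, hence non-increasing in k).
    ``coefficients`` is the flat real-basis coefficient vector of length
    ``(max_order + 1)**2`` ordered by degree then order; degrees beyond the
    rank-saturation point of the vertex sample carry zeros.
    """

    max_order: int
    coefficients: np.ndarray
    order_errors: np.ndarray  # length max_order + 1, entry k = RMS error at degree k
    mean_radius: float
    fitted_max_order: int
    regularization: float | None = None

    @property
    def reconstruction_errors(self) -> np.ndarray:
        """Errors at orders 1..max_order (the marker convention)."""
        return self.order_errors[1:]


def fit_sh(
    mapping: SphericalMapping, max_order: int = 85, rms_floor: float = 1e-12
) -> SHModel:
    """Fit ``r(theta, phi)`` in the real SH basis, degree by degree.

    Degree blocks are orthogonalized incrementally against the fitted
    subspace, so the per-order residuals come from properly nested
    least-squares fits.  Once the residual hits the floor (or the design
    saturates the vertex count) higher degrees cannot improve the fit and
    the error curve is continued flat.
    """
    r = np.asarray(mapping.radii, dtype=float)
    n = r.size
    if n < n_sh_coefficients(max_order):
        warnings.warn(
            f"{n} vertices < {n_sh_coefficients(max_order)} coefficients at "
            f"max_order={max_order}; the expansion is rank-limited",
            stacklevel=2,
        )
    scale = float(np.sqrt(np.mean(r**2))) or 1.0
    resid = r.copy()
    q_basis = np.empty((n, 0))
    design_blocks: list[np.ndarray] = []
    order_errors = np.empty(max_order + 1)
    fitted_max = max_order
    saturated = False
    for tau in range(max_order + 1):
        if saturated:
            order_errors[tau] = order_errors[tau - 1]
            continue
        block = real_sh_degree_block(tau, mapping.theta, mapping.phi)
        design_blocks.append(block)
        proj = block - q_basis @ (q_basis.T @ block)
        proj = proj - q_basis @ (q_basis.T @ proj)  # re-orthogonalize
        u, s, _ = np.linalg.svd(proj, full_matrices=False)
        keep = u[:, s > 1e-10 * max(1.0, s[0] if s.size else 1.0)]
        if keep.size:
            resid = resid - keep @ (keep.T @ resid)
            q_basis = np.hstack([q_basis, keep])
        order_errors[tau] = float(np.sqrt(np.mean(resid**2)))
        if order_errors[tau] <= rms_floor * scale or q_basis.shape[1] >= n:
            saturated = True
            fitted_max = tau

    design = np.hstack(design_blocks)
    coef_fit, _, rank, _ = np.linalg.lstsq(design, r, rcond=None)
    regularization = None
    if rank < design.shape[1]:
        # rank-deficient design: ridge keeps the coefficient report stable
        regularization = 1e-8
        gram = design.T @ design
        gram[np.diag_indices_from(gram)] += regularization
        coef_fit = np.linalg.solve(gram, design.T @ r)
    coefficients = np.zeros(n_sh_coefficients(max_order))
    coefficients[: coef_fit.size] = coef_fit
    return SHModel(
        max_order=max_order,
        coefficients=coefficients,
        order_errors=order_errors,
        mean_radius=float(r.mean()),
        fitted_max_order=fitted_max,
        regularization=regularization,
    )


def shape_feature_vector(
    sh_model: SHModel, n_markers: int = 85, normalize: bool = True
) -> FeatureVector:
    """Markers 1..n_markers: RMS reconstruction error at each truncation order.

    With ``normalize`` the errors are divided by the mean radius, making the
    markers scale-invariant measures of surface complexity.
    """
    if sh_model.max_order < n_markers:
        raise ValueError(
            f"model fitted to order {sh_model.max_order} < {n_markers} markers"
        )
    errors = sh_model.order_errors[1 : n_markers + 1].copy()
    if normalize:
        errors /= sh_model.mean_radius
    names = [f"sh_err_o{k:02d}" for k in range(1, n_markers + 1)]
    return FeatureVector(names, errors)


def shape_features_from_mask(
    lesion_mask: np.ndarray,
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    max_vertices: int = 2000,
    ar_config: ARConfig | None = None,
    max_order: int = 85,
    normalize: bool = True,
) -> FeatureVector:
    """Mask -> mesh -> sphere map -> SH fit -> 85 error markers, end to end.

    If the relaxation runs out of cycles while folds inherited from the
    voxelized projection remain, it is retried with a doubled cycle budget
    (up to three times) — the relaxation removes folds monotonically on
    near-star-shaped lesions, it just may need longer.
    """
    mesh = mesh_from_mask(lesion_mask, voxel_spacing, max_vertices=max_vertices)
    origin = choose_origin(mesh, lesion_mask, voxel_spacing)
    config = ar_config if ar_config is not None else ARConfig()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rank-limited fits are expected here
        for attempt in range(4):
            try:
                mapping = attraction_repulsion(mesh, origin, config)
                break
            except SphericalMappingError:
                if attempt == 3:
                    raise
                config = ARConfig(
                    c_a1=config.c_a1,
                    c_a2=config.c_a2,
                    c_r=config.c_r,
                    max_cycles=config.max_cycles * 2,
                    displacement_tol=config.displacement_tol,
                )
        model = fit_sh(mapping, max_order=max_order)
    return shape_feature_vector(model, n_markers=max_order, normalize=normalize)
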