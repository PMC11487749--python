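"""Vertex-wise gyrification index (GI) on triangulated cortical surfaces.

The local GI of a vertex is the ratio of buried-plus-visible cortical (pial)
area to the visible envelope area within a circular region of interest: a
geodesic disc is grown on an *outer smoothed surface* that tightly wraps the
pial surface, the pial patch corresponding to that disc is found by
nearest-point correspondence, and the ratio of patch area to disc area is the
local GI. Whole-brain GI is the unweighted mean over all pial vertices;
regional GI averages within a vertex label map.

The outer smoothed surface is built by voxelizing the pial mesh, filling it,
morphologically closing it with a spherical element (bridging over sulci),
extracting the isosurface and applying Taubin smoothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import sparse
from scipy.ndimage import binary_fill_holes, distance_transform_edt
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

log = logging.getLogger(__name__)

__all__ = [
    "GIConfig",
    "outer_smoothed_surface",
    "local_gi",
    "whole_brain_gi",
    "regional_gi",
    "vertex_areas",
]


@dataclass(frozen=True)
class GIConfig:
    """Geometry parameters of the GI computation (all lengths in mm).

    Defaults target neonatal-scale surfaces: a 20 mm ROI (smaller than the
    25 mm used for adult cortex, reflecting neonatal head size) and a 10 mm
    closing radius, large enough to bridge sulci but not gross concavities.
    `outer_vertex_stride` subsamples the envelope vertices at which discs are
    grown (a speed knob; values up to 4 change whole-brain GI by well under
    a percent on the synthetic surfaces).
    """

    closing_radius: float = 10.0
    voxel_size: float = 1.0
    roi_radius: float = 20.0
    outer_vertex_stride: int = 1
    smoothing_iterations: int = 10
    field_smoothing_iterations: int = 2
    max_grid_voxels: int = 60_000_000

    def validate(self) -> None:
        if min(self.closing_radius, self.voxel_size, self.roi_radius) <= 0:
            raise ValueError("closing_radius, voxel_size and roi_radius must be > 0")
        if self.roi_radius <= self.voxel_size:
            raise ValueError("roi_radius must exceed voxel_size")
        if self.outer_vertex_stride < 1:
            raise ValueError("outer_vertex_stride must be >= 1")
        if self.smoothing_iterations < 0 or self.field_smoothing_iterations < 0:
            raise ValueError("smoothing iteration counts must be >= 0")


def _check_closed(mesh: trimesh.Trimesh, name: str) -> None:
    if mesh.body_count != 1:
        raise ValueError(f"{name} surface has {mesh.body_count} components; expected one")
    if not mesh.is_watertight:
        raise ValueError(f"{name} surface is not closed (open or non-manifold edges)")


def vertex_areas(mesh: trimesh.Trimesh) -> np.ndarray:
    """Lumped per-vertex areas: one third of each incident face area."""
    areas = np.zeros(len(mesh.vertices))
    np.add.at(areas, mesh.faces.ravel(), np.repeat(mesh.area_faces / 3.0, 3))
    return areas


def outer_smoothed_surface(pial: trimesh.Trimesh, cfg: GIConfig) -> trimesh.Trimesh:
    """Build the outer smoothed envelope that tightly wraps a pial surface.

    Pipeline: voxelize at ``cfg.voxel_size`` -> fill interior -> morphological
    closing with a spherical element of ``cfg.closing_radius`` (implemented by
    Euclidean distance-transform thresholding, equivalent to dilation followed
    by erosion with a Euclidean ball) -> marching-cubes isosurface -> Taubin
    smoothing. For a convex input the closing is (up to voxelization) the
    identity, so the envelope area tracks the input area.
    """
    cfg.validate()
    _check_closed(pial, "pial")

    pitch = cfg.voxel_size
    r_vox = cfg.closing_radius / pitch
    pad = int(np.ceil(r_vox)) + 2

    extents = pial.extents
    est = np.prod((extents / pitch) + 2 * pad + 4)
    if est > cfg.max_grid_voxels:
        raise ValueError(
            f"voxel grid would need ~{est:.0f} voxels (cap {cfg.max_grid_voxels}); "
            "increase voxel_size"
        )

    vg = pial.voxelized(pitch).fill()
    filled = np.pad(np.asarray(vg.matrix, dtype=bool), pad)

    # Closing = dilation then erosion with a Euclidean ball of radius r_vox,
    # via distance-transform thresholding. The erosion surface is extracted
    # from the continuous inward EDT at level r_vox + 0.75: the rasterized
    # voxel shell and the centre-to-centre distances bias the level set
    # outward by about three quarters of a voxel, and this fixed sub-voxel
    # compensation keeps the envelope tight (near-identity on convex bodies).
    # The small epsilon keeps the level off exact EDT lattice values, which
    # would produce degenerate marching-cubes triangles.
    dilated = distance_transform_edt(~filled) <= r_vox
    dilated = binary_fill_holes(dilated)
    depth = distance_transform_edt(dilated)

    verts, faces, _, _ = marching_cubes(
        depth.astype(np.float32), level=r_vox + 0.75 - 1e-4
    )
    idx_coords = verts - pad  # back to the unpadded voxel index frame
    world = trimesh.transformations.transform_points(idx_coords, vg.transform)
    env = trimesh.Trimesh(vertices=world, faces=faces, process=True)
    env.update_faces(env.nondegenerate_faces())
    env.remove_unreferenced_vertices()
    if env.body_count > 1:
        env = max(env.split(only_watertight=False), key=lambda m: m.area)
    if cfg.smoothing_iterations > 0:
        # nu chosen to satisfy the Taubin stability bound 0 < 1/lamb - 1/nu < 0.1
        trimesh.smoothing.filter_taubin(
            env, lamb=0.5, nu=0.51, iterations=cfg.smoothing_iterations
        )
    ratio = env.area / pial.area
    log.info("outer envelope: area %.1f mm^2 (%.3f of pial area)", env.area, ratio)
    return env


def _edge_graph(mesh: trimesh.Trimesh) -> sparse.csr_matrix:
    edges = mesh.edges_unique
    lengths = mesh.edges_unique_length
    n = len(mesh.vertices)
    g = sparse.coo_matrix(
        (np.r_[lengths, lengths], (np.r_[edges[:, 0], edges[:, 1]], np.r_[edges[:, 1], edges[:, 0]])),
        shape=(n, n),
    )
    return g.tocsr()


def local_gi(
    pial: trimesh.Trimesh,
    outer: trimesh.Trimesh,
    cfg: GIConfig,
    chunk: int = 256,
) -> np.ndarray:
    """Per-pial-vertex local GI via circular ROIs on the outer envelope.

    For every retained envelope vertex (stride-subsampled): grow a geodesic
    disc of radius ``cfg.roi_radius`` (Dijkstra over mesh edges, an upper
    bound on the exact geodesic), collect the pial vertices whose nearest
    envelope vertex lies in the disc, and take (pial patch area) / (disc
    area) using lumped vertex areas. Values are then propagated to every pial
    vertex from its nearest retained envelope vertex.

    Returns one local-GI value per pial vertex.
    """
    cfg.validate()
    _check_closed(pial, "pial")
    _check_closed(outer, "outer")

    n_outer = len(outer.vertices)
    sources = np.arange(0, n_outer, cfg.outer_vertex_stride)
    graph = _edge_graph(outer)
    a_outer = vertex_areas(outer)
    a_pial = vertex_areas(pial)

    # pial -> nearest envelope vertex; pial area attached to each envelope vertex
    _, nearest_out = cKDTree(outer.vertices).query(pial.vertices, workers=-1)
    attached = np.bincount(nearest_out, weights=a_pial, minlength=n_outer)

    lgi_src = np.empty(len(sources))
    for start in range(0, len(sources), chunk):
        idx = sources[start : start + chunk]
        dist = dijkstra(graph, directed=False, indices=idx, limit=cfg.roi_radius)
        in_disc = np.isfinite(dist)
        disc_area = in_disc @ a_outer
        patch_area = in_disc @ attached
        empty = patch_area <= 0
        if empty.any():
            v = idx[np.argmax(empty)]
            raise ValueError(
                f"empty pial patch for envelope vertex {v}: pial/outer "
                "correspondence failed (is the envelope enclosing the pial?)"
            )
        lgi_src[start : start + chunk] = patch_area / disc_area

    _, nearest_src = cKDTree(outer.vertices[sources]).query(pial.vertices, workers=-1)
    field = lgi_src[nearest_src]

    # One-ring averaging over the pial graph: the overlapping-ROI construction
    # is locally smooth by design, and this damps the residual discretization
    # dips from the hard disc membership without moving the mean.
    if cfg.field_smoothing_iterations > 0:
        adj = _edge_graph(pial)
        adj.data[:] = 1.0
        deg = np.asarray(adj.sum(axis=1)).ravel()
        for _ in range(cfg.field_smoothing_iterations):
            field = (adj @ field + field) / (deg + 1.0)

    frac_below = float(np.mean(field < 1.0))
    log.info(
        "local GI: mean %.3f, range [%.3f, %.3f], %.1f%% of vertices below 1",
        field.mean(), field.min(), field.max(), 100 * frac_below,
    )
    return field


def whole_brain_gi(field: np.ndarray, labels: np.ndarray | None = None) -> float:
    """Unweighted mean local GI over all pial vertices.

    When two hemisphere fields are supplied, concatenate them first: the
    whole-brain value is the mean over the union of vertex sets, not the mean
    of per-hemisphere means. Vertices with label 0 (medial wall / unassigned)
    are excluded when a label array is given.
    """
    field = np.asarray(field, dtype=float)
    if field.size == 0:
        raise ValueError("empty GI field")
    if labels is not None:
        labels = np.asarray(labels)
        if labels.shape != field.shape:
            raise ValueError("labels not aligned to field")
        field = field[labels != 0]
        if field.size == 0:
            raise ValueError("no labelled vertices (all label 0)")
    return float(field.mean())


def regional_gi(
    field: np.ndarray,
    labels: np.ndarray,
    name_map: dict[int, str] | None = None,
) -> dict:
    """Per-region unweighted mean of vertex local GI.

    Label 0 is treated as medial wall / unassigned and omitted. If `name_map`
    is given, only the listed labels are reported (a requested label with no
    vertices is an error) and keys are the mapped names; otherwise every
    nonzero label present is reported under its integer key.
    """
    field = np.asarray(field, dtype=float)
    labels = np.asarray(labels)
    if field.shape != labels.shape:
        raise ValueError("labels not aligned to field")
    if name_map is None:
        wanted = {int(k): int(k) for k in np.unique(labels) if k != 0}
    else:
        wanted = {int(k): v for k, v in name_map.items() if k != 0}
    out = {}
    for lab, key in wanted.items():
        mask = labels == lab
        if not mask.any():
            raise ValueError(f"region label {lab} has zero vertices")
        out[key] = float(field[mask].mean())
    return out
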