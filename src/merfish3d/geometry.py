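"""Mesh-normal layer thickness and interventricular-septum classification.

Anatomical layers are closed, outward-oriented triangle meshes.  For
each vertex of the outermost (epicardial) mesh a ray is cast along the
*inward* (negated) vertex normal; the distances between consecutive
intersections with the inner layer meshes are the local layer
thicknesses (e.g. epicardium -> hybrid = compact thickness, hybrid ->
endocardium = hybrid thickness, epicardium -> endocardium = free wall
thickness).  The interventricular septum (IVS) — where an epicardial
normal passes between the two ventricular cavities — is excluded from
free-wall measurements via a five-case intersection-pattern
classification.

Per-vertex normals are trimesh's area-weighted averages of incident face
normals; ray casting is a vectorized Moller-Trumbore ray-triangle
intersector over the full face set (mesh sizes here are a few thousand
faces, so no spatial index is needed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import trimesh

__all__ = [
    "ray_mesh_intersections",
    "endocardial_ivs_labels",
    "classify_ivs",
    "layer_thickness",
]

_RAY_OFFSET = 1e-6  # nudge origins off the surface to avoid self-hits
_EPS = 1e-12

IVS, LEFT_WALL, RIGHT_WALL = "IVS", "left-wall", "right-wall"


def _ray_hits(
    origin: np.ndarray, direction: np.ndarray, mesh: trimesh.Trimesh
) -> np.ndarray:
    """All positive hit distances of one ray (Moller-Trumbore, vectorized
    over every face)."""
    tri = mesh.triangles  # (n_faces, 3, 3)
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    pvec = np.cross(direction, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > _EPS
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = origin - v0
    u = np.einsum("ij,ij->i", tvec, pvec) * inv_det
    qvec = np.cross(tvec, e1)
    v = qvec @ direction * inv_det
    t = np.einsum("ij,ij->i", qvec, e2) * inv_det
    hit = ok & (u >= -_EPS) & (v >= -_EPS) & (u + v <= 1 + _EPS) & (t > _RAY_OFFSET)
    ts = np.sort(t[hit])
    if len(ts) > 1:
        # rays through shared edges/vertices hit several faces at one point
        keep = np.concatenate([[True], np.diff(ts) > 1e-7 * np.maximum(ts[1:], 1.0)])
        ts = ts[keep]
    return ts


def ray_mesh_intersections(
    origin: np.ndarray, direction: np.ndarray, mesh: trimesh.Trimesh
) -> np.ndarray:
    """Sorted positive hit distances of one ray against a mesh.

    Returns an empty array when the ray misses.  Rays grazing exactly in
    a face plane are retried with a minutely perturbed direction.
    """
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    t = _ray_hits(origin, direction, mesh)
    if len(t) == 0:
        jitter = direction + 1e-9 * np.array([1.0, -1.0, 1.0])
        jitter /= np.linalg.norm(jitter)
        t = _ray_hits(origin, jitter, mesh)
    return t


def _batched_first_hits(
    origins: np.ndarray, directions: np.ndarray, mesh: trimesh.Trimesh
) -> tuple[np.ndarray, np.ndarray]:
    """First-hit distance (NaN on miss) and hit location per ray."""
    origins = np.asarray(origins, dtype=float)
    directions = np.asarray(directions, dtype=float)
    n = len(origins)
    t = np.full(n, np.nan)
    pts = np.full((n, 3), np.nan)
    for i in range(n):
        hits = _ray_hits(origins[i], directions[i], mesh)
        if len(hits):
            t[i] = hits[0]
            pts[i] = origins[i] + hits[0] * directions[i]
    return t, pts


def endocardial_ivs_labels(
    endo: trimesh.Trimesh, other_endo: trimesh.Trimesh
) -> np.ndarray:
    """Boolean IVS flag per endocardial vertex (mutual-intersection rule).

    A vertex belongs to the septum if its outward normal intersects the
    opposite ventricle's endocardial mesh.
    """
    t, _ = _batched_first_hits(endo.vertices, endo.vertex_normals, other_endo)
    return np.isfinite(t)


def classify_ivs(
    left_endo: trimesh.Trimesh,
    right_endo: trimesh.Trimesh | None,
    epi: trimesh.Trimesh,
) -> pd.DataFrame:
    """Label every epicardial vertex as IVS, left wall, or right wall.

    Each epicardial vertex casts its inward normal and the intersection
    pattern decides among five cases: (1) no endocardial hit -> IVS;
    (2)/(3) first hit lands on an IVS-labeled region of the right/left
    endocardium -> IVS; (4)/(5) first hit lands on a non-IVS region of
    the right/left endocardium -> right/left wall.  When both endocardia
    are hit the nearest hit wins.  With no right endocardium (single-
    ventricle input), cases (2)/(4) cannot occur.
    """
    inward = -epi.vertex_normals
    left_ivs = (
        endocardial_ivs_labels(left_endo, right_endo)
        if right_endo is not None
        else np.zeros(len(left_endo.vertices), dtype=bool)
    )
    t_left, p_left = _batched_first_hits(epi.vertices, inward, left_endo)
    if right_endo is not None:
        right_ivs = endocardial_ivs_labels(right_endo, left_endo)
        t_right, p_right = _batched_first_hits(epi.vertices, inward, right_endo)
    else:
        t_right = np.full(len(epi.vertices), np.nan)
        p_right = np.full((len(epi.vertices), 3), np.nan)

    labels = []
    cases = []
    for i in range(len(epi.vertices)):
        tl, tr = t_left[i], t_right[i]
        if np.isnan(tl) and np.isnan(tr):
            labels.append(IVS)
            cases.append(1)
            continue
        use_right = (not np.isnan(tr)) and (np.isnan(tl) or tr < tl)
        if use_right:
            vid = int(np.argmin(np.linalg.norm(right_endo.vertices - p_right[i], axis=1)))
            if right_ivs[vid]:
                labels.append(IVS)
                cases.append(2)
            else:
                labels.append(RIGHT_WALL)
                cases.append(4)
        else:
            vid = int(np.argmin(np.linalg.norm(left_endo.vertices - p_left[i], axis=1)))
            if left_ivs[vid]:
                labels.append(IVS)
                cases.append(3)
            else:
                labels.append(LEFT_WALL)
                cases.append(5)
    return pd.DataFrame({"vertex": np.arange(len(epi.vertices)),
                         "label": labels, "case": cases})


def layer_thickness(
    epi: trimesh.Trimesh,
    layer_meshes: list[trimesh.Trimesh],
    layer_names: list[str] | None = None,
    ivs_labels: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-vertex thicknesses from consecutive inward-normal intersections.

    ``layer_meshes`` are ordered outer to inner (e.g. hybrid,
    endocardial, Purkinje); for each non-IVS epicardial vertex the first
    hit distance to each layer is recorded and consecutive differences
    give the named layer thicknesses — the first name spans epicardium to
    the first layer.  ``total`` is the epicardium-to-innermost distance,
    equal to the sum of the per-layer thicknesses wherever every hit
    exists.  Vertices with an inverted hit order (inner mesh hit before
    an outer one) are flagged, and missing intersections yield NaN.
    """
    if layer_names is None:
        layer_names = [f"layer_{i}" for i in range(len(layer_meshes))]
    if len(layer_names) != len(layer_meshes):
        raise ValueError("one name per layer mesh required")
    inward = -epi.vertex_normals
    n = len(epi.vertices)
    hits = np.full((n, len(layer_meshes)), np.nan)
    for j, mesh in enumerate(layer_meshes):
        t, _ = _batched_first_hits(epi.vertices, inward, mesh)
        hits[:, j] = t
    out = pd.DataFrame({"vertex": np.arange(n)})
    if ivs_labels is not None:
        label_map = dict(zip(ivs_labels["vertex"], ivs_labels["label"]))
        out["label"] = [label_map.get(i, "") for i in range(n)]
        measurable = out["label"] != IVS
    else:
        measurable = np.ones(n, dtype=bool)
    prev = np.zeros(n)
    inverted = np.zeros(n, dtype=bool)
    for j, name in enumerate(layer_names):
        thick = hits[:, j] - prev
        inverted |= thick < 0
        out[name] = np.where(measurable, thick, np.nan)
        prev = np.where(np.isnan(hits[:, j]), prev, hits[:, j])
    out["total"] = np.where(measurable, hits[:, -1], np.nan)
    out["inverted_order"] = inverted
    for name in layer_names + ["total"]:
        out.loc[inverted, name] = np.nan
    return out
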