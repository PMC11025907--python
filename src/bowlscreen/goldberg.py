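"""Goldberg polyhedron model of the compound eye.

A Goldberg polyhedron GP(m, n) is the dual of the (m, n) geodesic
subdivision of the icosahedron: it has 12 pentagonal faces (at the
icosahedral vertices) and ``10*T - 10`` hexagonal faces with
``T = m^2 + m*n + n^2``.  GP(3, 3) (T = 27) has 272 faces — 260 hexagons
and 12 pentagons — 540 vertices and 810 edges, and serves as a simplified
model observer: one hexagonal face covers roughly the visual angle of
nine Drosophila ommatidia.

The raw construction (planar barycentric lattice projected to the
sphere) leaves the hexagon solid angles spread over several percent;
:func:`equalize_areas` relaxes the face-center generators on the sphere
until the hexagons are equal-area to a configurable tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull

from ._sphere import polygon_solid_angle

__all__ = ["GoldbergModel", "build_goldberg", "equalize_areas", "export_obj"]

_PHI = (1.0 + np.sqrt(5.0)) / 2.0


def _icosahedron():
    v = []
    for a in (-1.0, 1.0):
        for b in (-_PHI, _PHI):
            v += [(0.0, a, b), (a, b, 0.0), (b, 0.0, a)]
    verts = np.array(v)
    verts /= np.linalg.norm(verts[0])
    hull = ConvexHull(verts)
    return verts, hull.simplices


@dataclass
class GoldbergModel:
    """Goldberg polyhedron with faces indexed by their generator direction.

    ``generators`` are the unit face-center directions (one per face);
    ``vertices`` the polyhedron corners (one per geodesic triangle);
    ``faces`` lists vertex indices counter-clockwise seen from outside.
    """

    generators: np.ndarray
    vertices: np.ndarray
    faces: list
    triangles: np.ndarray = field(repr=False)  # geodesic triangles (gen indices)
    m: int = 0
    n: int = 0

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return sum(len(f) for f in self.faces) // 2

    @property
    def pentagon_ids(self) -> np.ndarray:
        return np.array([i for i, f in enumerate(self.faces) if len(f) == 5])

    @property
    def hexagon_ids(self) -> np.ndarray:
        return np.array([i for i, f in enumerate(self.faces) if len(f) == 6])

    def face_centroids(self) -> np.ndarray:
        """Unit outward direction of each face (vertex mean, normalized)."""
        cents = np.array([self.vertices[f].mean(axis=0) for f in self.faces])
        return cents / np.linalg.norm(cents, axis=1, keepdims=True)

    def face_solid_angles(self) -> np.ndarray:
        return np.array([polygon_solid_angle(self.vertices[f]) for f in self.faces])

    def face_vertices(self, i: int) -> np.ndarray:
        return self.vertices[self.faces[i]]


def _geodesic_points(m: int, n: int) -> np.ndarray:
    """Vertices of the (m, n) geodesic icosahedron (10T + 2 unit points)."""
    verts, tris = _icosahedron()
    # Eisenstein basis for the triangular lattice.
    e1 = np.array([1.0, 0.0])
    e2 = np.array([0.5, np.sqrt(3.0) / 2.0])
    p1 = m * e1 + n * e2
    # rotate p1 by +60 degrees to get the third master-triangle corner
    c, s = 0.5, np.sqrt(3.0) / 2.0
    p2 = np.array([c * p1[0] - s * p1[1], s * p1[0] + c * p1[1]])
    mat = np.stack([p1, p2], axis=1)  # columns
    inv = np.linalg.inv(mat)
    span = m + abs(n) + 1
    pts = []
    for i in range(-span, 2 * span):
        for j in range(-span, 2 * span):
            p = i * e1 + j * e2
            lam12 = inv @ p
            lam0 = 1.0 - lam12.sum()
            lam = np.array([lam0, lam12[0], lam12[1]])
            if np.all(lam > -1e-9) and np.all(lam < 1.0 + 1e-9):
                pts.append(lam)
    bary = np.array(pts)
    out = []
    for tri in tris:
        a, b, c3 = verts[tri]
        q = bary @ np.stack([a, b, c3])
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        out.append(q)
    allpts = np.concatenate(out)
    # dedupe points shared by adjacent icosahedral faces
    order = np.lexsort(np.round(allpts / 1e-6).astype(np.int64).T)
    allpts = allpts[order]
    keep = [0]
    for idx in range(1, len(allpts)):
        if np.linalg.norm(allpts[idx] - allpts[keep[-1]]) > 1e-6:
            keep.append(idx)
    uniq = allpts[keep]
    # a final pass catches near-duplicates split by the lexsort
    hull = ConvexHull(uniq)
    return uniq[sorted(set(hull.vertices))]


def _dualize(generators: np.ndarray, triangles: np.ndarray):
    """Vertices (triangle circum-directions as centroids) and ordered faces."""
    cents = generators[triangles].mean(axis=1)
    cents /= np.linalg.norm(cents, axis=1, keepdims=True)
    n_gen = len(generators)
    incident = [[] for _ in range(n_gen)]
    for t, tri in enumerate(triangles):
        for g in tri:
            incident[g].append(t)
    faces = []
    for g in range(n_gen):
        tids = incident[g]
        center = generators[g]
        # order incident triangle centroids counter-clockwise around g
        ref = cents[tids[0]] - center
        ref -= center * (ref @ center)
        ref /= np.linalg.norm(ref)
        ref2 = np.cross(center, ref)
        vecs = cents[tids] - center
        ang = np.arctan2(vecs @ ref2, vecs @ ref)
        faces.append([tids[k] for k in np.argsort(ang)])
    return cents, faces


def build_goldberg(m: int = 3, n: int = 3) -> GoldbergModel:
    """Construct GP(m, n) as the dual of the geodesic icosahedral sphere."""
    if m == 0 and n == 0:
        raise ValueError("GP(0, 0) is undefined")
    if m < 0 or n < 0:
        raise ValueError("m and n must be non-negative")
    generators = _geodesic_points(m, n)
    hull = ConvexHull(generators)
    tris = hull.simplices.copy()
    # orient all triangles outward
    cents = generators[tris].mean(axis=1)
    normals = np.cross(
        generators[tris[:, 1]] - generators[tris[:, 0]],
        generators[tris[:, 2]] - generators[tris[:, 0]],
    )
    flip = np.einsum("ij,ij->i", normals, cents) < 0
    tris[flip] = tris[flip][:, ::-1]
    vertices, faces = _dualize(generators, tris)
    return GoldbergModel(
        generators=generators, vertices=vertices, faces=faces, triangles=tris, m=m, n=n
    )


def _hex_adjacency(model: GoldbergModel):
    """Pairs of adjacent hexagonal faces (generators sharing a triangle edge)."""
    hex_ids = set(model.hexagon_ids.tolist())
    pairs = set()
    for tri in model.triangles:
        for a, b in ((0, 1), (1, 2), (2, 0)):
            i, j = int(tri[a]), int(tri[b])
            if i in hex_ids and j in hex_ids:
                pairs.add((min(i, j), max(i, j)))
    return np.array(sorted(pairs))


def equalize_areas(
    model: GoldbergModel,
    tol: float = 0.01,
    max_iter: int = 2000,
    step: float = 0.35,
) -> GoldbergModel:
    """Relax generators on the sphere until hexagon solid angles agree.

    Diffusion scheme: every hexagon generator moves toward adjacent
    hexagon generators whose faces are larger than its own (expanding its
    face into theirs) and away from smaller ones, then the dual is
    rebuilt with unchanged topology.  Pentagon generators (the
    icosahedral vertices) stay fixed, preserving the symmetry; pentagon
    areas absorb the residual.  Stops when the hexagon solid-angle spread
    is within ``±tol`` of the mean.
    """
    gens = model.generators.copy()
    tris = model.triangles
    pairs = _hex_adjacency(model)
    ii, jj = pairs[:, 0], pairs[:, 1]
    spread = np.inf
    for _ in range(max_iter):
        current = GoldbergModel(gens, *_dualize(gens, tris), triangles=tris,
                                m=model.m, n=model.n)
        omega = current.face_solid_angles()
        hex_omega = omega[current.hexagon_ids]
        mean = hex_omega.mean()
        spread = np.max(np.abs(hex_omega - mean)) / mean
        if spread <= tol:
            return current
        diff = (omega[jj] - omega[ii]) / mean
        force = np.zeros_like(gens)
        delta = gens[jj] - gens[ii]
        # shared edge between faces i and j moves toward whichever face is
        # larger when BOTH generators shift in that direction
        np.add.at(force, ii, step * diff[:, None] * delta)
        np.add.at(force, jj, step * diff[:, None] * delta)
        gens = gens + force
        gens /= np.linalg.norm(gens, axis=1, keepdims=True)
    raise RuntimeError(
        f"area equalization did not converge: spread {spread:.4f} after {max_iter} iters"
    )


def export_obj(model: GoldbergModel, path) -> None:
    """Write the polyhedron as a Wavefront OBJ with polygonal faces."""
    with open(path, "w") as fh:
        for v in model.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in model.faces:
            fh.write("f " + " ".join(str(i + 1) for i in f) + "\n")
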