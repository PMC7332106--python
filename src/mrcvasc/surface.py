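"""Triangulated growth surfaces.

The growth substrate is a closed, orientable triangle mesh Γ (positions in
mm).  Real cortical hemispheres come from imaging; here a synthetic
hemisphere-pair generator stands in for them: an ellipsoidal base shape with a
smooth medial groove (so the surface reads as a left/right pair) and an
optional sinusoidal fold displacement emulating gyri/sulci.  The surface is
star-shaped about the origin, smooth and genus-0 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh


@dataclass
class TriSurface:
    """A closed triangulated surface with cached per-triangle areas (mm^2)."""

    vertices: np.ndarray  # (V, 3) float, mm
    triangles: np.ndarray  # (F, 3) int
    triangle_areas: np.ndarray = field(init=False)
    total_area: float = field(init=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be an (F, 3) index array")
        if self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices):
            raise ValueError("triangle references an invalid vertex index")
        v = self.vertices
        t = self.triangles
        cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        self.triangle_areas = 0.5 * np.linalg.norm(cross, axis=1)
        if np.any(self.triangle_areas <= 0.0):
            raise ValueError("degenerate (zero-area) triangle in surface")
        self.total_area = float(self.triangle_areas.sum())

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.triangles, process=False
        )

    def euler_characteristic(self) -> int:
        m = self.as_trimesh()
        return int(m.euler_number)

    def is_closed(self) -> bool:
        return bool(self.as_trimesh().is_watertight)

    def triangle_centroids(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)

    def triangle_adjacency(self) -> list[list[int]]:
        """Edge-adjacent triangle neighbours, by shared mesh edge."""
        adj: list[list[int]] = [[] for _ in range(self.n_triangles)]
        for a, b in self.as_trimesh().face_adjacency:
            adj[a].append(int(b))
            adj[b].append(int(a))
        return adj

    def sample_points(
        self, n: int, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        """Area-uniform random points on the surface.

        Returns (points (n,3), triangle indices (n,)).  Consumption order:
        triangle draw, then barycentric draw.
        """
        probs = self.triangle_areas / self.total_area
        tri = rng.choice(self.n_triangles, size=n, p=probs)
        bary = sample_barycentric(n, rng)
        pts = np.einsum("ij,ijk->ik", bary, self.vertices[self.triangles[tri]])
        return pts, tri


def sample_barycentric(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform barycentric coordinates via the square-root construction."""
    r1 = np.sqrt(rng.random(n))
    r2 = rng.random(n)
    return np.stack([1.0 - r1, r1 * (1.0 - r2), r1 * r2], axis=1)


def _radial_shape(
    dirs: np.ndarray,
    semi_axes: tuple[float, float, float],
    fold_amplitude: float,
    fold_wavenumber: int,
    groove_depth: float,
    groove_width: float,
) -> np.ndarray:
    """Radius r(u) of the synthetic hemisphere pair along unit directions u."""
    a, b, c = semi_axes
    ux, uy, uz = dirs[:, 0], dirs[:, 1], dirs[:, 2]
    r_ell = 1.0 / np.sqrt((ux / a) ** 2 + (uy / b) ** 2 + (uz / c) ** 2)
    # Smooth medial groove along the x = 0 plane: hemisphere-pair appearance
    # without a crease (keeps the surface star-shaped and C^1).
    groove = 1.0 - groove_depth * np.exp(-((ux / groove_width) ** 2))
    r = r_ell * groove
    if fold_amplitude > 0.0:
        theta = np.arccos(np.clip(uz, -1.0, 1.0))
        phi = np.arctan2(uy, ux)
        k = int(fold_wavenumber)
        # sin(theta)^2 envelope kills the displacement at the poles where phi
        # is undefined; integer wavenumber keeps it continuous in phi.
        disp = (
            fold_amplitude
            * np.sin(theta) ** 2
            * np.sin(k * theta)
            * np.cos(k * phi)
        )
        r = r + disp
    return r


def make_synthetic_surface(
    semi_axes: tuple[float, float, float] = (34.0, 27.0, 24.0),
    fold_amplitude: float = 0.0,
    fold_wavenumber: int = 8,
    subdivisions: int = 5,
    groove_depth: float = 0.08,
    groove_width: float = 0.18,
) -> TriSurface:
    """Build the synthetic hemisphere-pair surface.

    Parameters
    ----------
    semi_axes:
        Ellipsoid semi-axes in mm; all must be positive.
    fold_amplitude:
        Radial fold amplitude in mm.  0 gives the smooth ("simplified"-style)
        surface; > 0 strictly increases the total area at equal resolution.
    fold_wavenumber:
        Integer angular wavenumber of the folds.
    subdivisions:
        Icosphere subdivision level controlling mesh resolution; must give at
        least ~10^3 triangles (subdivisions >= 3).
    """
    if any(s <= 0 for s in semi_axes):
        raise ValueError("semi-axes must all be positive")
    if fold_amplitude < 0:
        raise ValueError("fold amplitude must be non-negative")
    if subdivisions < 3:
        raise ValueError("subdivisions < 3 yields fewer than 10^3 triangles")
    if not (0.0 <= groove_depth < 1.0):
        raise ValueError("groove depth must be in [0, 1)")
    base = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    dirs = np.asarray(base.vertices)
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    r = _radial_shape(
        dirs, semi_axes, fold_amplitude, fold_wavenumber, groove_depth, groove_width
    )
    if np.any(r <= 0):
        raise ValueError("fold amplitude too large: surface self-intersects")
    return TriSurface(dirs * r[:, None], np.asarray(base.faces))


def make_sphere_surface(radius: float, subdivisions: int = 4) -> TriSurface:
    """Plain icosphere; handy as an analytic fixture."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriSurface(np.asarray(m.vertices), np.asarray(m.faces))


def load_surface(path: str) -> TriSurface:
    """Load a PLY/STL/OFF triangle mesh."""
    m = trimesh.load_mesh(path, process=False)
    if not isinstance(m, trimesh.Trimesh):
        raise ValueError(f"{path} did not contain a single triangle mesh")
    return TriSurface(np.asarray(m.vertices), np.asarray(m.faces))


def save_surface(surface: TriSurface, path: str) -> None:
    surface.as_trimesh().export(path)
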