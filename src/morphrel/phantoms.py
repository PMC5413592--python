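"""Phantoms: synthetic structures with analytically known properties.

Voxel phantoms (Menger sponge, cubes, spheres, slabs, lines) have exact
fractal dimensionalities and volumes, so every estimator can be validated
without imaging data.  Mesh phantoms (icospheres, bumpy spheres, concentric
shells) provide analytic areas, thicknesses and controllable folding.
Multi-session measurement matrices are drawn from the one-way random-effects
model y_ij = mu + b_i + e_ij, the generative model under which the ICC(1)
reliability coefficient is defined; the true reliability is
rho = sigma_b^2 / (sigma_b^2 + sigma_w^2).

All randomness is driven by an explicit per-call seed; there is no global RNG
state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage

from .io_formats import BinaryMask, SessionMatrix, SurfaceMesh

MAX_MENGER_LEVEL = 5
MAX_SUBDIVISIONS = 7


# ---------------------------------------------------------------------------
# Voxel phantoms
# ---------------------------------------------------------------------------

_MENGER_TILE = None


def _menger_tile() -> np.ndarray:
    """3x3x3 generator tile: keep all cells except face centers and the core."""
    global _MENGER_TILE
    if _MENGER_TILE is None:
        idx = np.indices((3, 3, 3))
        center = (idx == 1).sum(axis=0)  # how many coordinates equal 1
        _MENGER_TILE = center < 2  # 20 of 27 cells survive
    return _MENGER_TILE


def menger_sponge(level: int) -> BinaryMask:
    """Menger sponge of the given level on a 3^level grid.

    Exactly 20^level foreground voxels; fractal dimensionality
    log 20 / log 3 ~= 2.7268.
    """
    if level < 0:
        raise ValueError("level must be non-negative")
    if level > MAX_MENGER_LEVEL:
        raise ValueError(f"level {level} > {MAX_MENGER_LEVEL} (grid would be 3^level per side)")
    data = np.ones((1, 1, 1), dtype=bool)
    tile = _menger_tile()
    for _ in range(level):
        data = np.kron(data, tile)
    return BinaryMask(data=data)


def filled_cube(side: int) -> BinaryMask:
    """Solid cube filling its own side^3 grid (FD -> 3)."""
    if side < 1:
        raise ValueError("side must be >= 1")
    return BinaryMask(data=np.ones((side, side, side), dtype=bool))


def hollow_cube(side: int) -> BinaryMask:
    """One-voxel-thick cube shell: the filled cube minus its 6-connected
    interior erosion (FD -> 2)."""
    full = filled_cube(side).data
    interior = ndimage.binary_erosion(
        full, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return BinaryMask(data=full & ~interior)


def sphere_mask(radius: float, grid: int, voxel_size_mm: float = 1.0) -> BinaryMask:
    """Digital ball: voxels whose center lies within ``radius`` of the grid center."""
    if radius >= grid / 2:
        raise ValueError(f"radius {radius} would clip at the {grid}-voxel grid")
    coords = np.indices((grid, grid, grid)) - (grid - 1) / 2.0
    data = (coords**2).sum(axis=0) <= radius**2
    return BinaryMask(data=data, voxel_size_mm=np.full(3, voxel_size_mm))


def slab_mask(side: int, thickness: int = 1) -> BinaryMask:
    """Sheet spanning the grid in-plane, ``thickness`` voxels thick, centered
    along z (FD -> 2 for thin sheets)."""
    data = np.zeros((side, side, side), dtype=bool)
    z0 = (side - thickness) // 2
    data[:, :, z0 : z0 + thickness] = True
    return BinaryMask(data=data)


def line_mask(length: int) -> BinaryMask:
    """One-voxel line spanning the grid along x, centered in y/z (FD -> 1)."""
    data = np.zeros((length, length, length), dtype=bool)
    data[:, length // 2, length // 2] = True
    return BinaryMask(data=data)


def random_blob(
    grid: int = 32, seed: int = 0, n_seeds: int = 8, dilate_iters: int = 3
) -> BinaryMask:
    """Random connected-ish blob for property testing: scattered seed voxels
    dilated a few times, kept away from the grid border."""
    rng = np.random.default_rng(seed)
    data = np.zeros((grid, grid, grid), dtype=bool)
    margin = grid // 4
    pts = rng.integers(margin, grid - margin, size=(n_seeds, 3))
    data[pts[:, 0], pts[:, 1], pts[:, 2]] = True
    data = ndimage.binary_dilation(data, iterations=dilate_iters)
    return BinaryMask(data=data)


# ---------------------------------------------------------------------------
# Mesh phantoms
# ---------------------------------------------------------------------------

@dataclass
class BumpySphereSpec:
    """Sphere perturbed radially by a seeded band-limited spherical-harmonic field."""

    radius: float = 50.0
    max_degree: int = 32
    amplitude: float = 2.0
    seed: int = 0
    subdivisions: int = 5

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.amplitude >= self.radius:
            raise ValueError("amplitude must be < radius (no self-intersection)")
        if self.subdivisions > MAX_SUBDIVISIONS:
            raise ValueError(f"subdivisions capped at {MAX_SUBDIVISIONS}")


def icosphere(radius: float = 50.0, subdivisions: int = 4) -> SurfaceMesh:
    """Geodesic icosphere: closed, outward-oriented, area -> 4 pi r^2."""
    if subdivisions > MAX_SUBDIVISIONS:
        raise ValueError(f"subdivisions capped at {MAX_SUBDIVISIONS}")
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(vertices=np.asarray(m.vertices), faces=np.asarray(m.faces))


def bumpy_sphere(spec: BumpySphereSpec) -> SurfaceMesh:
    """Icosphere with each vertex displaced radially by a random real-SH field.

    The field uses bands l = 1..max_degree with independent standard-normal
    coefficients and is renormalized so its maximum absolute displacement
    equals ``spec.amplitude``.  Same seed, same mesh.
    """
    base = icosphere(radius=spec.radius, subdivisions=spec.subdivisions)
    if spec.amplitude == 0:
        return base
    from .spharm import real_sh_basis

    u = base.vertices / np.linalg.norm(base.vertices, axis=1)[:, None]
    basis = real_sh_basis(u, spec.max_degree)[:, 1:]  # drop l=0 (pure inflation)
    rng = np.random.default_rng(spec.seed)
    coeffs = rng.standard_normal(basis.shape[1])
    field = basis @ coeffs
    peak = np.max(np.abs(field))
    if peak == 0:
        return base
    radial = spec.radius + spec.amplitude * field / peak
    return SurfaceMesh(vertices=radial[:, None] * u, faces=base.faces)


def concentric_shells(
    r_inner: float, r_outer: float, subdivisions: int = 3
) -> tuple[SurfaceMesh, SurfaceMesh]:
    """Two concentric icospheres sharing topology; analytic gap r_outer - r_inner."""
    if r_inner <= 0 or r_inner >= r_outer:
        raise ValueError("need 0 < r_inner < r_outer")
    outer = icosphere(radius=r_outer, subdivisions=subdivisions)
    inner = SurfaceMesh(
        vertices=outer.vertices * (r_inner / r_outer), faces=outer.faces.copy()
    )
    return inner, outer


def dumbbell(
    radius: float = 30.0,
    waist: float = 0.45,
    width: float = 0.35,
    subdivisions: int = 4,
) -> SurfaceMesh:
    """Two-lobed "peanut": an icosphere radially pinched around its equator.

    r(u) = radius * (1 - waist * exp(-(u_z / width)^2)) for unit direction u.
    Closed, star-shaped about the origin, and non-convex, so its convex hull
    has strictly less area than the surface itself.
    """
    if not 0 < waist < 1:
        raise ValueError("waist must be in (0, 1)")
    base = icosphere(radius=1.0, subdivisions=subdivisions)
    u = base.vertices / np.linalg.norm(base.vertices, axis=1)[:, None]
    r = radius * (1.0 - waist * np.exp(-((u[:, 2] / width) ** 2)))
    return SurfaceMesh(vertices=r[:, None] * u, faces=base.faces)


# ---------------------------------------------------------------------------
# Session-matrix simulation
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponentsSpec:
    """One-way random-effects generative model for test-retest sessions.

    True reliability: rho = sigma_between^2 / (sigma_between^2 + sigma_within^2).
    Defaults mirror a 30-subject, 10-session test-retest design with high
    reliability (rho = 0.8).
    """

    n_subjects: int = 30
    k_sessions: int = 10
    grand_mean: float = 2.5
    sigma_between: float = 2.0
    sigma_within: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.k_sessions < 2:
            raise ValueError("need n >= 2 subjects and k >= 2 sessions")
        if self.sigma_between < 0 or self.sigma_within < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.sigma_between == 0 and self.sigma_within == 0:
            raise ValueError("at least one variance component must be positive")

    @property
    def true_icc(self) -> float:
        vb, vw = self.sigma_between**2, self.sigma_within**2
        return vb / (vb + vw)


def simulate_sessions(spec: VarianceComponentsSpec, metric_name: str = "simulated") -> SessionMatrix:
    """Draw y_ij = mu + b_i + e_ij, b_i ~ N(0, sigma_b^2), e_ij ~ N(0, sigma_w^2)."""
    rng = np.random.default_rng(spec.seed)
    b = rng.normal(0.0, spec.sigma_between, size=spec.n_subjects)
    e = rng.normal(0.0, spec.sigma_within, size=(spec.n_subjects, spec.k_sessions))
    values = spec.grand_mean + b[:, None] + e
    return SessionMatrix(
        values=values,
        subject_ids=[f"sub-{i + 1:03d}" for i in range(spec.n_subjects)],
        session_ids=[f"ses-{j + 1:02d}" for j in range(spec.k_sessions)],
        metric_name=metric_name,
    )


__all__ = [
    "BumpySphereSpec",
    "VarianceComponentsSpec",
    "menger_sponge",
    "filled_cube",
    "hollow_cube",
    "sphere_mask",
    "slab_mask",
    "line_mask",
    "random_blob",
    "icosphere",
    "bumpy_sphere",
    "concentric_shells",
    "dumbbell",
    "simulate_sessions",
]
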