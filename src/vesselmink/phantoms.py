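"""Synthetic tubular-network phantoms with known geometry and topology.

Ground truth drives every downstream test: a phantom network is built from
tubes (open centrelines) and rings (closed centrelines), so its component
count k and independent-cycle count L are known by construction and its Euler
characteristic is k − L.  Loops are created by welding ring pairs with a
guaranteed overlap blob (two centrelines crossing at a point, tubes merging in
one contractible region), which keeps the ground-truth topology independent of
the digital connectivity convention.

Rendering emulates the confocal degradations the segmentation stage must undo:
anisotropic Gaussian blur (optical sectioning), additive Gaussian noise,
impulse ("speckle") noise, and a constant-plus-gradient background emulating
tissue autofluorescence (which rises with specimen age in real material).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_io import BinaryVolume, ZStack

__all__ = [
    "NetworkSpec",
    "RenderSpec",
    "make_tube",
    "make_torus",
    "make_hollow_sphere",
    "make_network",
    "render_zstack",
    "make_cohort",
    "standard_phantom",
    "STANDARD_RENDER",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Parameters of one synthetic capillary network.

    ``n_loops`` counts independent cycles across the whole network; loops are
    assigned to components round-robin.  ``tortuosity`` is the amplitude (in
    voxels) of a sinusoidal perturbation of every centreline.
    """

    n_components: int = 2
    n_loops: int = 1
    radius_mean: float = 3.0
    radius_sd: float = 0.0
    tortuosity: float = 1.0
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    seed: int = 0

    def __post_init__(self):
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.n_loops < 0:
            raise ValueError("n_loops must be >= 0")
        if self.radius_mean < 1:
            raise ValueError("radius_mean must be >= 1 voxel")
        if self.radius_sd < 0 or self.tortuosity < 0:
            raise ValueError("radius_sd and tortuosity must be >= 0")


@dataclass(frozen=True)
class RenderSpec:
    """Confocal rendering parameters (all in voxel/intensity units)."""

    psf_sigma: tuple[float, float, float] = (1.0, 1.0, 2.0)  # (x, y, z)
    noise_sd: float = 20.0
    speckle_rate: float = 0.001
    speckle_amplitude: float = 200.0
    background_level: float = 10.0
    background_gradient: float = 5.0
    signal_level: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if any(s < 0 for s in self.psf_sigma) or min(
            self.noise_sd, self.speckle_rate, self.speckle_amplitude,
            self.background_level, self.background_gradient, self.signal_level,
        ) < 0:
            raise ValueError("render parameters must be >= 0")


class GenerationError(RuntimeError):
    """Raised when a network cannot be packed into the requested grid."""


def _segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each of ``points`` (N,3) to the segment a-b."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip(((points - a) @ ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def _rasterize_polyline(polyline: np.ndarray, radius: float,
                        grid_shape, occ: np.ndarray | None = None) -> np.ndarray:
    """Set every voxel within ``radius`` of the polyline; works in (z,y,x)."""
    if occ is None:
        occ = np.zeros(grid_shape, dtype=bool)
    lo = np.maximum(np.floor(polyline.min(axis=0) - radius - 1).astype(int), 0)
    hi = np.minimum(np.ceil(polyline.max(axis=0) + radius + 2).astype(int),
                    np.array(grid_shape))
    if np.any(polyline < radius - 0.5) or np.any(
        polyline > np.array(grid_shape) - 1 - radius + 0.5
    ):
        raise ValueError("polyline exits the grid (needs radius clearance)")
    zz, yy, xx = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    pts = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1).astype(float)
    dist = np.full(len(pts), np.inf)
    for a, b in zip(polyline[:-1], polyline[1:]):
        np.minimum(dist, _segment_distance(pts, a, b), out=dist)
    inside = (dist <= radius).reshape(zz.shape)
    occ[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= inside
    return occ


def make_tube(centreline, radius: float, grid_shape) -> BinaryVolume:
    """Rasterize an open tube: all voxels within ``radius`` of the polyline.

    ``centreline`` is a sequence of (z, y, x) points; a bounds error is raised
    if the tube would leave the grid.
    """
    polyline = np.asarray(centreline, dtype=float)
    if polyline.ndim != 2 or polyline.shape[1] != 3 or len(polyline) < 2:
        raise ValueError("centreline must be an (N>=2, 3) array of points")
    occ = _rasterize_polyline(polyline, radius, tuple(grid_shape))
    return BinaryVolume(occupancy=occ)


def _ring_points(centre, R: float, normal_axis: int, chain_axis: int,
                 n_pts: int = 96, tortuosity: float = 0.0, rng=None) -> np.ndarray:
    """Closed circular centreline of radius R in a coordinate plane.

    The circle spans ``chain_axis`` and the remaining axis; an optional
    sinusoidal perturbation of amplitude ``tortuosity`` is applied along the
    normal, phased to vanish at the two chain-axis extremes of the circle so
    that weld points between consecutive rings are preserved exactly.
    """
    t = np.linspace(0, 2 * np.pi, n_pts, endpoint=False)
    t = np.append(t, t[0])
    third = next(a for a in range(3) if a not in (normal_axis, chain_axis))
    pts = np.tile(np.asarray(centre, float), (len(t), 1))
    pts[:, chain_axis] += R * np.cos(t)   # extremes (weld points) at t = 0, pi
    pts[:, third] += R * np.sin(t)
    if tortuosity > 0:
        k = 3 if rng is None else int(rng.integers(2, 5))
        pts[:, normal_axis] += tortuosity * np.sin(k * t)  # zero at t = 0, pi
    return pts


def make_torus(major_R: float, minor_r: float, grid_shape, centre=None) -> BinaryVolume:
    """Digitized solid torus (one component, one tunnel, no cavities)."""
    if not (major_R > minor_r >= 1):
        raise ValueError("need major_R > minor_r >= 1")
    grid_shape = tuple(grid_shape)
    if centre is None:
        centre = tuple((n - 1) / 2 for n in grid_shape)
    need = major_R + minor_r
    if any(c - need < -0.5 or c + need > n - 0.5 for c, n in zip(centre[1:], grid_shape[1:])) \
       or centre[0] - minor_r < -0.5 or centre[0] + minor_r > grid_shape[0] - 0.5:
        raise ValueError("torus does not fit in the grid")
    zz, yy, xx = np.mgrid[: grid_shape[0], : grid_shape[1], : grid_shape[2]]
    rho = np.sqrt((yy - centre[1]) ** 2 + (xx - centre[2]) ** 2)
    occ = (rho - major_R) ** 2 + (zz - centre[0]) ** 2 <= minor_r**2
    return BinaryVolume(occupancy=occ)


def make_hollow_sphere(outer_r: float, inner_r: float, grid_shape, centre=None) -> BinaryVolume:
    """Spherical shell: one component, no tunnels, one enclosed cavity (χ = 2)."""
    if not (outer_r > inner_r >= 1):
        raise ValueError("need outer_r > inner_r >= 1")
    grid_shape = tuple(grid_shape)
    if centre is None:
        centre = tuple((n - 1) / 2 for n in grid_shape)
    if any(c - outer_r < -0.5 or c + outer_r > n - 0.5 for c, n in zip(centre, grid_shape)):
        raise ValueError("sphere does not fit in the grid")
    zz, yy, xx = np.mgrid[: grid_shape[0], : grid_shape[1], : grid_shape[2]]
    d2 = (zz - centre[0]) ** 2 + (yy - centre[1]) ** 2 + (xx - centre[2]) ** 2
    occ = (d2 <= outer_r**2) & (d2 > inner_r**2)
    return BinaryVolume(occupancy=occ)


def _component_centrelines(spec: NetworkSpec, n_loops: int, rng,
                           box_lo: np.ndarray, box_hi: np.ndarray,
                           radius: float) -> list[np.ndarray]:
    """Centrelines of one component inside an axis-aligned box.

    0 loops → a single tortuous open tube; ℓ ≥ 1 loops → a chain of ℓ rings,
    consecutive rings crossing at exactly one point (welded), alternating
    normal axes so crossings are transversal.
    """
    span = box_hi - box_lo
    centre = (box_lo + box_hi) / 2.0
    if n_loops == 0:
        n_pts = 40
        t = np.linspace(0.0, 1.0, n_pts)
        axis = int(np.argmax(span))
        others = [a for a in range(3) if a != axis]
        pts = np.tile(centre, (n_pts, 1))
        pts[:, axis] = box_lo[axis] + radius + 1 + t * (span[axis] - 2 * (radius + 1))
        k1, k2 = rng.integers(1, 4, size=2)
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        amp = spec.tortuosity
        pts[:, others[0]] += amp * np.sin(2 * np.pi * k1 * t + ph1)
        pts[:, others[1]] += amp * np.sin(2 * np.pi * k2 * t + ph2)
        return [pts]
    # chain of n_loops rings along the longest box axis; consecutive rings
    # cross at exactly one point (centres 2R apart, so ring j+1 passes through
    # ring j's chain-axis extreme), with alternating normals for transversality
    chain_axis = int(np.argmax(span))
    amp = spec.tortuosity
    margin = radius + amp + 1.0
    r_cross = min(span[a] for a in range(3) if a != chain_axis) / 2.0 - margin
    r_chain = (span[chain_axis] - 2 * (radius + 1)) / (2.0 * n_loops)
    R = min(r_cross, r_chain)
    if R < max(2.0, 1.5 * radius):
        raise GenerationError(
            "box too small for a welded ring chain; enlarge grid or reduce loops"
        )
    normals = [a for a in range(3) if a != chain_axis]
    rings = []
    pos = centre.copy()
    pos[chain_axis] = box_lo[chain_axis] + radius + 1 + R
    for j in range(n_loops):
        normal = normals[j % 2]
        rings.append(_ring_points(pos, R, normal_axis=normal,
                                  chain_axis=chain_axis,
                                  tortuosity=amp, rng=rng))
        pos = pos.copy()
        pos[chain_axis] += 2 * R
    return rings


def make_network(spec: NetworkSpec):
    """Rasterize a network with known (components, loops) ground truth.

    Returns ``(BinaryVolume, ground_truth)`` with ground truth fields
    ``components``, ``loops``, ``centrelines`` (list of per-component lists of
    polylines), ``radii`` and ``min_gap`` (the guaranteed inter-component
    clearance in voxels).
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    shape = np.array(spec.grid_shape)
    k = spec.n_components
    # distribute loops round-robin over components
    loops_per = [spec.n_loops // k + (1 if i < spec.n_loops % k else 0) for i in range(k)]
    radii = np.clip(rng.normal(spec.radius_mean, spec.radius_sd, size=k),
                    1.0, None)
    clearance = 2 * float(radii.max()) + 3.0
    # partition the grid into k slabs along the longest axis, inset by clearance/2
    axis = int(np.argmax(shape))
    slab = shape[axis] / k
    if slab < 4 * spec.radius_mean + clearance:
        raise GenerationError(
            f"grid {spec.grid_shape} too small for {k} components with clearance "
            f"{clearance:.1f}; advise a larger grid"
        )
    occ = np.zeros(tuple(shape), dtype=bool)
    centrelines: list[list[np.ndarray]] = []
    for i in range(k):
        lo = np.zeros(3)
        hi = shape.astype(float) - 1
        lo[axis] = i * slab + clearance / 2
        hi[axis] = (i + 1) * slab - 1 - clearance / 2
        lo += 1
        hi -= 1
        lines = _component_centrelines(spec, loops_per[i], rng, lo, hi, radii[i])
        for line in lines:
            _rasterize_polyline(line, radii[i], tuple(shape), occ)
        centrelines.append(lines)
    truth = {
        "components": k,
        "loops": spec.n_loops,
        "centrelines": centrelines,
        "radii": radii.tolist(),
        "min_gap": clearance - 2 * float(radii.max()),
    }
    return BinaryVolume(occupancy=occ), truth


def render_zstack(vol: BinaryVolume, spec: RenderSpec) -> ZStack:
    """Render a binary vessel model as a noisy confocal-like z-stack.

    intensity = blur(foreground · signal) + background + noise, clipped at 0;
    fully deterministic given ``spec.seed``; never mutates ``vol``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    img = vol.occupancy.astype(np.float64) * spec.signal_level
    sx, sy, sz = spec.psf_sigma
    if max(spec.psf_sigma) > 0:
        img = ndimage.gaussian_filter(img, sigma=(sz, sy, sx))
    nz = vol.shape[0]
    grad = np.linspace(0.0, 1.0, nz)[:, None, None]
    img = img + spec.background_level + spec.background_gradient * grad
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    if spec.speckle_rate > 0:
        mask = rng.random(img.shape) < spec.speckle_rate
        img = img + mask * spec.speckle_amplitude
    np.clip(img, 0.0, None, out=img)
    return ZStack(voxels=img, spacing=vol.spacing,
                  meta={"render_seed": spec.seed, "snr": (spec.signal_level /
                        spec.noise_sd if spec.noise_sd else np.inf)})


#: Rendering conditions of the standard recovery phantom: SNR 5 with the
#: anisotropic (1,1,2)-voxel PSF of ~1 µm optical sections.
STANDARD_RENDER = RenderSpec(psf_sigma=(1.0, 1.0, 2.0), noise_sd=20.0,
                             signal_level=100.0, speckle_rate=0.001,
                             speckle_amplitude=200.0, background_level=10.0,
                             background_gradient=5.0, seed=7)


def standard_phantom(seed: int = 7):
    """The standard segmentation-recovery fixture: a 2-component, 1-loop
    network of radius-4 tubes (a typical ~8 µm capillary at ~1 µm sampling)
    in an 80³ grid, plus its SNR-5 rendering."""
    spec = NetworkSpec(n_components=2, n_loops=1, radius_mean=4.0,
                       tortuosity=1.5, grid_shape=(80, 80, 80), seed=seed)
    vol, truth = make_network(spec)
    stack = render_zstack(vol, RenderSpec(**{**STANDARD_RENDER.__dict__, "seed": seed}))
    return vol, truth, stack


def default_effect_model(age: float, seed: int, grid_shape=(64, 64, 64)) -> NetworkSpec:
    """Age → network parameters encoding the qualitative cohort findings:
    loop density and tortuosity rise in later years (inflection near 60),
    calibre dips mid-life then recovers."""
    loops = 1 + int(max(0.0, age - 60.0) // 8)
    tort = 1.0 + 1.5 * max(0.0, age - 60.0) / 25.0
    radius = 3.0 - 0.5 * np.exp(-((age - 55.0) / 20.0) ** 2)
    return NetworkSpec(n_components=2, n_loops=loops, radius_mean=float(radius),
                       tortuosity=float(tort), grid_shape=grid_shape, seed=seed)


def make_cohort(n_samples: int, age_range=(20.0, 84.0), effect_model=None,
                seed: int = 0, render: bool = False):
    """Generate a reproducible synthetic cohort.

    ``effect_model(age, seed) -> NetworkSpec`` maps age to network parameters
    (default :func:`default_effect_model`).  Returns ``(volumes, ages, truths)``
    where volumes are BinaryVolumes (or rendered ZStacks with ``render=True``).
    Per-sample seeds are split from ``seed`` with a counter-based scheme, so
    samples are independent and the cohort regenerates bit-identically.
    """
    if effect_model is None:
        effect_model = default_effect_model
    root = np.random.SeedSequence(seed)
    age_seq, *sample_seqs = root.spawn(n_samples + 1)
    ages = np.sort(np.random.default_rng(age_seq).uniform(*age_range, size=n_samples))
    volumes, truths = [], []
    for age, seq in zip(ages, sample_seqs):
        sub_seed = int(seq.generate_state(1)[0] % (2**31))
        spec = effect_model(float(age), sub_seed)
        vol, truth = make_network(spec)
        truth["age"] = float(age)
        truth["spec"] = spec
        if render:
            vol = render_zstack(vol, RenderSpec(**{**STANDARD_RENDER.__dict__,
                                                   "seed": sub_seed}))
        volumes.append(vol)
        truths.append(truth)
    return volumes, ages, truths
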