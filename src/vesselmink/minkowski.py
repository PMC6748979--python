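"""The four 3D Minkowski functionals of binary voxel volumes.

A binary volume is interpreted as the union of closed unit cubes (one per
foreground voxel), which realizes the standard (26-connected foreground,
6-connected background) digital topology.  The module provides:

* exact integer Euler characteristic via a 2x2x2 configuration lookup table
  derived from the cubical cell complex;
* a Crofton-type surface-area estimate (intercept counts along 13 discrete
  directions, weighted by the spherical-Voronoi solid angles of the direction
  set) that converges to the true area for smooth bodies, plus the exact
  digital boundary-face count as a diagnostic;
* a Crofton plane-sweep mean-breadth estimate (sum of 2D Euler characteristics
  of axis-perpendicular slices), normalized so a ball's mean breadth equals its
  diameter;
* exact polyhedral intrinsic volumes of the voxel complex, used by the
  additivity check, where the union/intersection of two bodies is formed at
  the cell level so that shared lower-dimensional faces are retained (this is
  the setting in which additivity V(A∪B)=V(A)+V(B)−V(A∩B) holds exactly);
* an exhaustive Betti-number oracle for small grids.

Euler-characteristic conventions: under (26,6), loops (tunnels) in a vessel
network lower the Euler number, so a network of k components with L independent
loops and no cavities has χ = k − L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import SphericalVoronoi

from .core_io import BinaryVolume, MFVector

__all__ = [
    "ConfigCounts",
    "config_counts",
    "minkowski_3d",
    "betti_numbers_small",
    "mf_additivity_check",
    "cell_complex_counts",
    "euler_from_counts",
    "polyhedral_functionals",
]

# ---------------------------------------------------------------------------
# 2x2x2 configuration machinery
# ---------------------------------------------------------------------------

# Bit order of a 2x2x2 window: bit = dz*4 + dy*2 + dx for offsets (dz,dy,dx)
# in {0,1}^3.  A window anchored at padded position p covers voxels
# p + (dz-1, dy-1, dx-1); the window "owns" the lattice vertex shared by all
# eight voxels, the three edges/faces leaving it in positive directions, and
# the single voxel at offset (1,1,1).


def _bit(config: int, dz: int, dy: int, dx: int) -> int:
    return (config >> (dz * 4 + dy * 2 + dx)) & 1


def _build_euler_lut() -> np.ndarray:
    """Per-configuration Euler increments for the (26,6) pair.

    Each window contributes the alternating cell count (V − E + F − C) of the
    cells it owns in the closed cubical complex; a cell is present when any of
    its incident voxels is foreground.
    """
    lut = np.zeros(256, dtype=np.int64)
    for c in range(256):
        bits = np.array(
            [[[_bit(c, dz, dy, dx) for dx in (0, 1)] for dy in (0, 1)] for dz in (0, 1)],
            dtype=bool,
        )
        v = int(bits.any())
        # edges leaving the central vertex along +z, +y, +x
        e = int(bits[1, :, :].any()) + int(bits[:, 1, :].any()) + int(bits[:, :, 1].any())
        # faces spanning (+z,+y), (+z,+x), (+y,+x)
        f = int(bits[1, 1, :].any()) + int(bits[1, :, 1].any()) + int(bits[:, 1, 1].any())
        q = int(bits[1, 1, 1])
        lut[c] = v - e + f - q
    return lut


def _build_euler_lut_6() -> np.ndarray:
    """Euler increments for the complementary (6,26) pair (open-cell counting)."""
    lut = np.zeros(256, dtype=np.int64)
    for c in range(256):
        bits = np.array(
            [[[_bit(c, dz, dy, dx) for dx in (0, 1)] for dy in (0, 1)] for dz in (0, 1)],
            dtype=bool,
        )
        v = int(bits.all())
        e = int(bits[1, :, :].all()) + int(bits[:, 1, :].all()) + int(bits[:, :, 1].all())
        f = int(bits[1, 1, :].all()) + int(bits[1, :, 1].all()) + int(bits[:, 1, 1].all())
        q = int(bits[1, 1, 1])
        # chi = sum over open cells of (-1)^(3 - dim)
        lut[c] = q - f + e - v
    return lut


_EULER_LUT_26 = _build_euler_lut()
_EULER_LUT_6 = _build_euler_lut_6()


@dataclass(frozen=True)
class ConfigCounts:
    """Histogram of the 256 possible 2x2x2 voxel configurations.

    Computed over the volume padded with one background layer, so the counts
    sum to (nz+1)(ny+1)(nx+1) and every boundary cell is seen.
    """

    counts: np.ndarray
    shape: tuple[int, int, int]

    def __post_init__(self):
        if self.counts.shape != (256,) or np.any(self.counts < 0):
            raise ValueError("counts must be 256 non-negative integers")
        expected = int(np.prod([n + 1 for n in self.shape]))
        if int(self.counts.sum()) != expected:
            raise ValueError(
                f"counts sum {int(self.counts.sum())} != {expected} windows"
            )


def _as_occ(vol) -> np.ndarray:
    if isinstance(vol, BinaryVolume):
        return vol.occupancy
    occ = np.asarray(vol)
    return occ > 0 if occ.dtype != bool else occ


def config_counts(vol) -> ConfigCounts:
    """Count every 2x2x2 neighbourhood configuration of the padded volume."""
    occ = _as_occ(vol)
    p = np.pad(occ, 1).astype(np.uint8)
    code = np.zeros(tuple(n - 1 for n in p.shape), dtype=np.uint8)
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                w = 1 << (dz * 4 + dy * 2 + dx)
                code += w * p[dz : dz + code.shape[0],
                              dy : dy + code.shape[1],
                              dx : dx + code.shape[2]]
    counts = np.bincount(code.ravel(), minlength=256).astype(np.int64)
    return ConfigCounts(counts=counts, shape=occ.shape)


# ---------------------------------------------------------------------------
# Cell-complex counts (independent of the LUT path)
# ---------------------------------------------------------------------------


def cell_complex_counts(vol) -> tuple[int, int, int, int]:
    """Distinct (vertices, edges, faces, cubes) of the closed cubical complex.

    Counted globally by OR-reductions over shifted copies; this route never
    touches the configuration histogram, so it serves as an independent oracle
    for the LUT-based Euler characteristic.
    """
    occ = _as_occ(vol)
    p = np.pad(occ, 1)
    n_cubes = int(occ.sum())
    n_faces = 0
    n_edges = 0
    for ax in range(3):
        a = np.moveaxis(p, ax, 0)
        n_faces += int((a[:-1] | a[1:]).sum())
        r = a[:, :-1, :] | a[:, 1:, :]
        r = r[:, :, :-1] | r[:, :, 1:]
        n_edges += int(r.sum())
    s = p[:-1] | p[1:]
    s = s[:, :-1] | s[:, 1:]
    s = s[:, :, :-1] | s[:, :, 1:]
    n_vertices = int(s.sum())
    return n_vertices, n_edges, n_faces, n_cubes


def euler_from_counts(cc: ConfigCounts, connectivity: str = "26-6") -> int:
    """Exact Euler characteristic from a configuration histogram."""
    lut = _EULER_LUT_26 if connectivity == "26-6" else _EULER_LUT_6
    return int(np.dot(cc.counts, lut))


def polyhedral_functionals(vol) -> np.ndarray:
    """Exact intrinsic-volume-based functionals of the voxel polyhedron.

    Returns ``[volume, surface, mean_breadth, euler]`` of the union of closed
    unit cubes, on the Minkowski normalization used throughout this package
    (surface = boundary area; a ball's mean breadth = its diameter).  These are
    exact valuations of the polyhedral body, hence exactly additive when
    union/intersection are taken at the cell level.
    """
    nV, nE, nF, nC = cell_complex_counts(vol)
    euler = nV - nE + nF - nC
    volume = float(nC)
    surface = 2.0 * (nF - 3 * nC)          # = exact digital boundary-face area
    v1 = 3 * nC - 2 * nF + nE              # intrinsic volume V1 of the polyhedron
    mean_breadth = v1 / 2.0                # ball-diameter normalization
    return np.array([volume, surface, mean_breadth, euler], dtype=np.float64)


# ---------------------------------------------------------------------------
# Crofton estimators
# ---------------------------------------------------------------------------

_CROFTON_OFFSETS = np.array(
    [
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    ],
    dtype=np.int64,
)

_weight_cache: dict[tuple[float, float, float], np.ndarray] = {}


def _direction_weights(spacing: tuple[float, float, float]) -> np.ndarray:
    """Solid-angle weight of each of the 13 lattice directions.

    The 26 signed physical direction vectors partition the unit sphere by a
    spherical Voronoi diagram; each unsigned direction gets the fractional
    area of its two antipodal cells.  Weights sum to 1.
    """
    key = tuple(float(s) for s in spacing)
    if key in _weight_cache:
        return _weight_cache[key]
    # offsets are (dz, dy, dx); physical step uses spacing (dx, dy, dz)
    phys = _CROFTON_OFFSETS.astype(float) * np.array([key[2], key[1], key[0]])
    unit = phys / np.linalg.norm(phys, axis=1, keepdims=True)
    pts = np.vstack([unit, -unit])
    sv = SphericalVoronoi(pts)
    areas = sv.calculate_areas()
    w = (areas[:13] + areas[13:]) / (4.0 * np.pi)
    _weight_cache[key] = w
    return w


def _crofton_surface(occ: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Surface area via intercept counts along 13 directions.

    For direction ω with one sampling line per perpendicular area a_d
    (a_d = voxel volume / step length), the number of foreground/background
    interfaces n_d estimates ∫_∂X |⟨n,ω⟩| dA / a_d; averaging |⟨n,ω⟩| over the
    sphere gives 1/2, hence S ≈ 2 Σ_d w_d n_d · vol_vox / len_d.
    """
    p = np.pad(occ, 1)
    w = _direction_weights(spacing)
    dxyz = np.array([spacing[2], spacing[1], spacing[0]])  # per-axis (z,y,x)
    vol_vox = float(np.prod(spacing))
    total = 0.0
    for (dz, dy, dx), wd in zip(_CROFTON_OFFSETS, w):
        # with a 1-voxel false border, wraparound only pairs border with border
        shifted = np.roll(p, (dz, dy, dx), axis=(0, 1, 2))
        n_d = int((p ^ shifted).sum())
        step = float(np.linalg.norm(np.array([dz, dy, dx]) * dxyz))
        total += wd * n_d * vol_vox / step
    return 2.0 * total


def _chi2d_slice_sum(occ: np.ndarray, axis: int) -> int:
    """Sum over slices perpendicular to ``axis`` of the 2D Euler characteristic.

    Each slice is treated as a union of closed unit squares, i.e. the 2D
    (8-foreground, 4-background) convention, consistent with (26,6) in 3D.
    """
    a = np.moveaxis(occ, axis, 0)
    p = np.pad(a, ((0, 0), (1, 1), (1, 1)))
    n_sq = int(p.sum())
    e1 = int((p[:, :-1, :] | p[:, 1:, :]).sum())
    e2 = int((p[:, :, :-1] | p[:, :, 1:]).sum())
    v = p[:, :-1, :] | p[:, 1:, :]
    n_v = int((v[:, :, :-1] | v[:, :, 1:]).sum())
    return n_v - e1 - e2 + n_sq


def _crofton_mean_breadth(occ: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Mean breadth by Crofton plane sweep over the three grid axes.

    For convex bodies ∫ χ(X ∩ plane_t) dt along direction ω equals the breadth
    in direction ω; averaging over directions gives the mean breadth (equal to
    the diameter for a ball).  The three axis directions are used, weighted
    equally — exact for axis-aligned boxes and within a few percent for
    digitized balls.
    """
    sp_axis = (spacing[2], spacing[1], spacing[0])  # spacing along (z, y, x)
    vals = [
        _chi2d_slice_sum(occ, ax) * sp_axis[ax] for ax in range(3)
    ]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------


def minkowski_3d(vol, units_mode: str = "voxel", connectivity: str | None = None,
                 extras: bool = False):
    """Compute the four 3D Minkowski functionals of a binary volume.

    Parameters
    ----------
    vol : BinaryVolume or bool ndarray
        The body; interpreted as closed voxels under (26,6) connectivity.
    units_mode : 'voxel' | 'physical'
        With 'physical', lengths are scaled by the volume's spacing (µm);
        with 'voxel', unit spacing is used regardless.
    connectivity : optional
        Override the volume's connectivity tag ('26-6' or '6-26').
    extras : bool
        If True, return ``(MFVector, dict)`` with diagnostic estimates:
        exact boundary-face surface, polyhedral mean breadth, and the raw
        integral of mean curvature (2π × mean breadth).

    Returns
    -------
    MFVector (and a diagnostics dict when ``extras``).
    """
    occ = _as_occ(vol)
    if units_mode == "physical" and isinstance(vol, BinaryVolume):
        spacing = vol.spacing
    else:
        spacing = (1.0, 1.0, 1.0)
    if connectivity is None:
        connectivity = vol.connectivity if isinstance(vol, BinaryVolume) else "26-6"

    if occ.size == 0 or not occ.any():
        mf = MFVector(0.0, 0.0, 0.0, 0, units_mode=units_mode)
        if extras:
            return mf, {"surface_area_faces": 0.0, "mean_breadth_poly": 0.0,
                        "mean_curvature_integral": 0.0}
        return mf

    cc = config_counts(occ)
    euler = euler_from_counts(cc, connectivity)
    volume = float(occ.sum()) * float(np.prod(spacing))
    surface = _crofton_surface(occ, spacing)
    breadth = _crofton_mean_breadth(occ, spacing)
    mf = MFVector(volume=volume, surface_area=surface, mean_breadth=breadth,
                  euler=euler, units_mode=units_mode)
    if extras:
        poly = polyhedral_functionals(occ)
        # exact counts are defined on the voxel lattice; reported in voxel units
        diag = {
            "surface_area_faces": float(poly[1]),
            "mean_breadth_poly": float(poly[2]),
            "mean_curvature_integral": 2.0 * np.pi * breadth,
        }
        return mf, diag
    return mf


def betti_numbers_small(vol) -> tuple[int, int, int]:
    """Betti numbers (b0, b1, b2) of a small volume, by exhaustive labelling.

    b0 = 26-connected foreground components; b2 = 6-connected background
    components fully enclosed (not touching the padded border); b1 follows from
    b0 − b1 + b2 = χ with χ taken from the independent global cell-complex
    count, not the configuration LUT.
    """
    occ = _as_occ(vol)
    if any(n > 20 for n in occ.shape):
        raise ValueError(f"exhaustive oracle limited to grids <= 20^3, got {occ.shape}")
    struct26 = np.ones((3, 3, 3), dtype=bool)
    _, b0 = ndimage.label(occ, structure=struct26)
    padded_bg = ~np.pad(occ, 1)
    struct6 = ndimage.generate_binary_structure(3, 1)
    lab, n_bg = ndimage.label(padded_bg, structure=struct6)
    border_labels = set(np.unique(np.concatenate([
        lab[0].ravel(), lab[-1].ravel(),
        lab[:, 0].ravel(), lab[:, -1].ravel(),
        lab[:, :, 0].ravel(), lab[:, :, -1].ravel(),
    ])))
    border_labels.discard(0)
    b2 = n_bg - len(border_labels)
    nV, nE, nF, nC = cell_complex_counts(occ)
    chi = nV - nE + nF - nC
    b1 = b0 + b2 - chi
    return int(b0), int(b1), int(b2)


def mf_additivity_check(a, b) -> dict[str, float]:
    """Additivity residuals MF(A∪B) + MF(A∩B) − MF(A) − MF(B) per functional.

    Bodies are the unions of closed voxels; union and intersection are formed
    on the cubical cell complexes, so A∩B keeps shared lower-dimensional faces
    (the polyhedral intersection, where Minkowski additivity is an identity).
    Functionals are the exact polyhedral valuations of
    :func:`polyhedral_functionals`; euler and volume residuals are integer
    identities (exactly 0), surface and mean breadth are exact rational
    valuations evaluated in floats (residual below 1e-9).
    """
    occ_a, occ_b = _as_occ(a), _as_occ(b)
    if occ_a.shape != occ_b.shape:
        raise ValueError(f"shape mismatch: {occ_a.shape} vs {occ_b.shape}")

    def cells(occ):
        # indicator arrays of (vertices, edges*3, faces*3, cubes) of K(occ)
        p = np.pad(occ, 1)
        out = {"cubes": occ.copy()}
        for ax in range(3):
            aa = np.moveaxis(p, ax, 0)
            out[f"face{ax}"] = aa[:-1] | aa[1:]
            r = aa[:, :-1, :] | aa[:, 1:, :]
            out[f"edge{ax}"] = r[:, :, :-1] | r[:, :, 1:]
        s = p[:-1] | p[1:]
        s = s[:, :-1] | s[:, 1:]
        out["verts"] = s[:, :, :-1] | s[:, :, 1:]
        return out

    def functionals(cell_sets) -> np.ndarray:
        nC = int(cell_sets["cubes"].sum())
        nF = sum(int(cell_sets[f"face{ax}"].sum()) for ax in range(3))
        nE = sum(int(cell_sets[f"edge{ax}"].sum()) for ax in range(3))
        nV = int(cell_sets["verts"].sum())
        euler = nV - nE + nF - nC
        return np.array(
            [float(nC), 2.0 * (nF - 3 * nC), (3 * nC - 2 * nF + nE) / 2.0, euler]
        )

    ka, kb = cells(occ_a), cells(occ_b)
    union = {k: ka[k] | kb[k] for k in ka}
    inter = {k: ka[k] & kb[k] for k in ka}
    resid = functionals(union) + functionals(inter) - functionals(ka) - functionals(kb)
    return {
        "volume": float(resid[0]),
        "surface_area": float(resid[1]),
        "mean_breadth": float(resid[2]),
        "euler": float(resid[3]),
    }
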