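"""Dilation analysis: Minkowski-functional signatures and the 40-feature summary.

The segmented vessel set is uniformly inflated by thresholding its exact
Euclidean distance transform at increasing radii ("balloon inflation"); the
four Minkowski functionals evaluated at each radius form the sample's four
*signatures*.  Each signature is then condensed into ten summary features
(moments and critical points), yielding a fixed 40-entry vector per sample.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .core_io import (
    BinaryVolume,
    CURVE_FEATURES,
    FeatureVector,
    MF_PREFIXES,
    MFSignature,
)
from .minkowski import minkowski_3d

__all__ = [
    "edt",
    "dilate_at",
    "signature",
    "default_radii",
    "normalize_for_report",
    "denormalize",
    "extract_features",
    "mean_feature_vector",
]


def edt(vol: BinaryVolume) -> np.ndarray:
    """Exact Euclidean distance (voxel units) to the nearest foreground voxel.

    Zero on foreground.  Anisotropic spacing is honoured through per-axis
    sampling weights expressed relative to the x–y pixel pitch, so distances
    stay in units of in-plane voxels (the convention used for dilation radii).
    With empty foreground the field is all +inf and a warning is issued.
    """
    occ = vol.occupancy
    if not occ.any():
        warnings.warn("empty foreground: distance field is infinite everywhere")
        return np.full(occ.shape, np.inf)
    dx = vol.spacing[0]
    sampling = (vol.spacing[2] / dx, vol.spacing[1] / dx, 1.0)  # (z, y, x)
    return ndimage.distance_transform_edt(~occ, sampling=sampling)


def dilate_at(dist: np.ndarray, r: float, template: BinaryVolume | None = None) -> BinaryVolume:
    """Threshold a distance field at radius ``r``: the dilated vessel set.

    ``r = 0`` returns exactly the original set (distance 0 ⇔ foreground).
    """
    if r < 0:
        raise ValueError("dilation radius must be >= 0")
    occ = dist <= r
    spacing = template.spacing if template is not None else (1.0, 1.0, 1.0)
    connectivity = template.connectivity if template is not None else "26-6"
    return BinaryVolume(occupancy=occ, spacing=spacing, connectivity=connectivity,
                        meta={"dilation_radius": float(r)})


def default_radii(mean_radius: float, cap: int = 25) -> np.ndarray:
    """Default integer radius grid 0..R with R = ceil(3 × mean vessel radius),
    capped (signature abscissas beyond ~25 voxels carry no extra structure at
    capillary scale)."""
    r_max = int(min(cap, max(2, np.ceil(3.0 * mean_radius))))
    return np.arange(0, r_max + 1, dtype=np.float64)


def signature(vol: BinaryVolume, radii) -> MFSignature:
    """Evaluate the four Minkowski functionals on dilated copies of ``vol``."""
    radii = np.asarray(radii, dtype=np.float64)
    if radii.ndim != 1 or len(radii) == 0 or radii[0] != 0 or np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be ascending and start at 0")
    dist = edt(vol)
    curves = [minkowski_3d(dilate_at(dist, r, template=vol)) for r in radii]
    return MFSignature(radii=radii, curves=curves)


def normalize_for_report(signatures: list[MFSignature]):
    """Normalize a collection of signatures for joint plotting/reporting.

    Volume, surface-area and mean-breadth curves are divided by the global
    maximum across the collection; Euler curves are affinely mapped by the
    global (min, max) range onto [0, 1].  Returns ``(normalized, params)``
    where ``params`` allows :func:`denormalize` to invert the map exactly.
    """
    if not signatures:
        raise ValueError("need at least one signature")
    params: dict[str, tuple[float, float]] = {}
    for prefix in ("vol", "surf_area", "mean_breadth"):
        gmax = max(float(s.curve(prefix).max()) for s in signatures)
        if gmax == 0:
            warnings.warn(f"{prefix}: zero maximum; leaving curves unscaled")
            gmax = 1.0
        params[prefix] = (0.0, gmax)
    lo = min(float(s.curve("euler3D").min()) for s in signatures)
    hi = max(float(s.curve("euler3D").max()) for s in signatures)
    if hi == lo:
        warnings.warn("euler3D: zero range; leaving curves unscaled")
        lo, hi = 0.0, 1.0
    params["euler3D"] = (lo, hi - lo)

    normalized = []
    for s in signatures:
        out = {"radius": s.radii}
        for prefix in MF_PREFIXES:
            shift, scale = params[prefix]
            out[prefix] = (s.curve(prefix) - shift) / scale
        normalized.append(out)
    return normalized, params


def denormalize(normalized: list[dict], params: dict) -> list[dict]:
    """Invert :func:`normalize_for_report` exactly."""
    out = []
    for n in normalized:
        d = {"radius": n["radius"]}
        for prefix in MF_PREFIXES:
            shift, scale = params[prefix]
            d[prefix] = n[prefix] * scale + shift
        out.append(d)
    return out


def _curve_features(y: np.ndarray, r: np.ndarray) -> dict[str, float]:
    """The ten summary features of one signature curve.

    var/std are population moments; maxima/minima break ties toward the
    smallest abscissa; the derivative is the forward difference Δy/Δr assigned
    to the left endpoint of each interval.
    """
    i_max = int(np.argmax(y))          # argmax returns the first (smallest r) tie
    i_min = int(np.argmin(y))
    dy = np.diff(y) / np.diff(r)
    i_dmax = int(np.argmax(dy))
    return {
        "var": float(np.var(y)),
        "std": float(np.std(y)),
        "mean": float(np.mean(y)),
        "median": float(np.median(y)),
        "max": float(y[i_max]),
        "maxScale": float(r[i_max]),
        "min": float(y[i_min]),
        "minScale": float(r[i_min]),
        "dmax": float(dy[i_dmax]),
        "dmaxScale": float(r[i_dmax]),
    }


def extract_features(sig: MFSignature) -> FeatureVector:
    """Condense one sample's four signatures into the named 40-feature vector."""
    if len(sig) < 2:
        raise ValueError("signature needs at least 2 radii (derivative undefined)")
    values: dict[str, float] = {}
    for prefix in MF_PREFIXES:
        feats = _curve_features(sig.curve(prefix), sig.radii)
        for name in CURVE_FEATURES:
            values[f"{prefix}_{name}"] = feats[name]
    return FeatureVector(values)


def mean_feature_vector(vectors: list[FeatureVector]) -> FeatureVector:
    """Unweighted mean of per-volume feature vectors (multi-FOV samples).

    Well defined because the underlying functionals are additive, so averages
    of their summaries are meaningful sample-level descriptors; note var/std
    are re-derived so the std²=var invariant holds after averaging.
    """
    if not vectors:
        raise ValueError("need at least one feature vector")
    import pandas as pd

    mean = pd.concat([v.as_series() for v in vectors], axis=1).mean(axis=1)
    vals = mean.to_dict()
    for p in MF_PREFIXES:
        vals[f"{p}_std"] = float(np.sqrt(max(vals[f"{p}_var"], 0.0)))
        # averaging can break max >= median >= min only through var/std; the
        # order stats themselves average monotonically, so nothing else to fix
    return FeatureVector(vals)
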