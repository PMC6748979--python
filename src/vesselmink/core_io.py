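"""Domain containers and I/O for the capillary morphometry pipeline.

The pipeline's data model is deliberately small:

* :class:`ZStack` — a raw confocal intensity volume with physical voxel spacing.
* :class:`BinaryVolume` — a segmented vessel model (1 = vessel, 0 = background)
  with a declared digital-connectivity convention.
* :class:`ThicknessMap` — per-voxel local vessel diameter.
* :class:`MFVector` / :class:`MFSignature` — the four 3D Minkowski functionals,
  at one dilation radius or as curves over radii.
* :class:`FeatureVector` — the fixed 40-entry summary of one sample's signatures.
* :class:`SampleTable` — a cohort table (samples x 40 features + age).

Axis convention: arrays are indexed ``(z, y, x)`` with ``z`` the optical-section
index; multi-page TIFF pages map to ``z``.  Spacing is stored as ``(dx, dy, dz)``
in micrometres per voxel.  Coordinates are 0-based.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ZStack",
    "BinaryVolume",
    "ThicknessMap",
    "MFVector",
    "MFSignature",
    "FeatureVector",
    "SampleTable",
    "FEATURE_NAMES",
    "MF_PREFIXES",
    "CURVE_FEATURES",
    "FormatError",
    "SchemaError",
    "read_zstack",
    "write_volume",
    "read_binary_volume",
    "read_thickness_map",
    "read_feature_table",
    "write_feature_table",
    "read_config",
    "get_logger",
    "stage_timer",
]

log = logging.getLogger("vesselmink")

#: The four Minkowski-functional prefixes, in canonical order.
MF_PREFIXES = ("vol", "surf_area", "mean_breadth", "euler3D")

#: The ten per-curve summary features, in canonical order.
CURVE_FEATURES = (
    "var",
    "std",
    "mean",
    "median",
    "max",
    "maxScale",
    "min",
    "minScale",
    "dmax",
    "dmaxScale",
)

#: Canonical 40 feature names: the 4 x 10 cross product, e.g. ``surf_area_dmax``.
FEATURE_NAMES = tuple(f"{p}_{f}" for p in MF_PREFIXES for f in CURVE_FEATURES)


class FormatError(ValueError):
    """Raised when an input file does not conform to the expected layout."""


class SchemaError(ValueError):
    """Raised when a tabular input is missing or has unexpected columns."""


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive lengths, got {spacing}")
    return spacing


@dataclass
class ZStack:
    """A 3D fluorescence intensity volume.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Non-negative finite intensities in arbitrary fluorescence units.
    spacing : (dx, dy, dz)
        Physical voxel size in micrometres.
    meta : dict
        Free-form provenance (sample id, age, acquisition notes).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.voxels.ndim}")
        if self.voxels.shape[0] < 2:
            raise ValueError("a z-stack needs at least 2 planes")
        if not np.all(np.isfinite(self.voxels)) or np.any(self.voxels < 0):
            raise ValueError("intensities must be finite and non-negative")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class BinaryVolume:
    """A segmented vessel model: 1 = vessel, 0 = everything else.

    ``connectivity`` declares the digital-topology pairing used for component
    labelling and the Euler number; the default ``"26-6"`` means 26-connected
    foreground with 6-connected background (closed-voxel interpretation).
    """

    occupancy: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    connectivity: str = "26-6"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        occ = np.asarray(self.occupancy)
        if occ.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={occ.ndim}")
        if occ.dtype != bool:
            vals = np.unique(occ)
            if not np.all(np.isin(vals, (0, 1, 255))):
                raise ValueError("occupancy must be strictly binary")
            occ = occ > 0
        self.occupancy = occ
        self.spacing = _check_spacing(self.spacing)
        if self.connectivity not in ("26-6", "6-26"):
            raise ValueError(f"unknown connectivity tag {self.connectivity!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    def count(self) -> int:
        return int(self.occupancy.sum())


@dataclass
class ThicknessMap:
    """Local vessel diameter (µm or voxels) at every foreground voxel, 0 outside."""

    diameters: np.ndarray
    source: BinaryVolume | None = None
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        d = np.asarray(self.diameters, dtype=np.float64)
        if d.ndim != 3:
            raise ValueError("diameters must be a 3D field")
        if np.any(d < 0):
            raise ValueError("diameters must be non-negative")
        self.diameters = d
        self.spacing = _check_spacing(self.spacing)
        if self.source is not None:
            fg = self.source.occupancy
            if d.shape != fg.shape:
                raise ValueError("diameters and source shapes differ")
            if np.any((d > 0) != fg):
                raise ValueError("diameters must be > 0 exactly on foreground voxels")


@dataclass(frozen=True)
class MFVector:
    """The four 3D Minkowski functionals of one binary body.

    ``euler`` is the exact integer Euler characteristic under the declared
    connectivity; ``units_mode`` records whether lengths are in voxels or µm.
    """

    volume: float
    surface_area: float
    mean_breadth: float
    euler: int
    units_mode: str = "voxel"

    def __post_init__(self):
        if self.volume < 0 or self.surface_area < 0:
            raise ValueError("volume and surface area must be non-negative")
        if self.euler != int(self.euler):
            raise ValueError("euler must be an integer")
        if self.units_mode not in ("voxel", "physical"):
            raise ValueError(f"bad units_mode {self.units_mode!r}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.volume, self.surface_area, self.mean_breadth, self.euler],
            dtype=np.float64,
        )


@dataclass
class MFSignature:
    """The four Minkowski curves over an ascending grid of dilation radii."""

    radii: np.ndarray
    curves: list[MFVector]

    def __post_init__(self):
        r = np.asarray(self.radii, dtype=np.float64)
        if r.ndim != 1 or len(r) != len(self.curves):
            raise ValueError("radii and curves must have the same length")
        if len(r) and r[0] != 0:
            raise ValueError("radii must start at 0")
        if np.any(np.diff(r) <= 0):
            raise ValueError("radii must be strictly increasing")
        vol = np.array([c.volume for c in self.curves])
        if np.any(np.diff(vol) < 0):
            raise ValueError("volume curve must be non-decreasing in radius")
        self.radii = r

    def __len__(self) -> int:
        return len(self.radii)

    def curve(self, prefix: str) -> np.ndarray:
        """Return one of the four curves by its feature prefix."""
        attr = {
            "vol": "volume",
            "surf_area": "surface_area",
            "mean_breadth": "mean_breadth",
            "euler3D": "euler",
        }[prefix]
        return np.array([getattr(c, attr) for c in self.curves], dtype=np.float64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "radius": self.radii,
                "vol": self.curve("vol"),
                "surf_area": self.curve("surf_area"),
                "mean_breadth": self.curve("mean_breadth"),
                "euler3D": self.curve("euler3D"),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MFSignature":
        curves = [
            MFVector(
                volume=row["vol"],
                surface_area=row["surf_area"],
                mean_breadth=row["mean_breadth"],
                euler=int(row["euler3D"]),
            )
            for _, row in df.iterrows()
        ]
        return cls(radii=df["radius"].to_numpy(), curves=curves)


class FeatureVector(Mapping):
    """The 40 named scalar features of one sample (Table-style naming).

    Behaves as an immutable mapping with exactly the canonical key set
    (``vol_var`` ... ``euler3D_dmaxScale``).
    """

    __slots__ = ("_values",)

    def __init__(self, values: Mapping[str, float]):
        missing = set(FEATURE_NAMES) - set(values)
        extra = set(values) - set(FEATURE_NAMES)
        if missing or extra:
            raise SchemaError(
                f"feature vector keys mismatch: missing={sorted(missing)}, "
                f"extra={sorted(extra)}"
            )
        self._values = {k: float(values[k]) for k in FEATURE_NAMES}
        for p in MF_PREFIXES:
            var, std = self._values[f"{p}_var"], self._values[f"{p}_std"]
            if abs(std * std - var) > 1e-6 * max(1.0, abs(var)):
                raise ValueError(f"{p}: std^2 != var ({std**2} vs {var})")
            lo, mid, hi = (
                self._values[f"{p}_min"],
                self._values[f"{p}_median"],
                self._values[f"{p}_max"],
            )
            if not (hi >= mid >= lo):
                raise ValueError(f"{p}: max >= median >= min violated")

    def __getitem__(self, key: str) -> float:
        return self._values[key]

    def __iter__(self) -> Iterator[str]:
        return iter(FEATURE_NAMES)

    def __len__(self) -> int:
        return len(FEATURE_NAMES)

    def as_series(self) -> pd.Series:
        return pd.Series(self._values, index=list(FEATURE_NAMES), dtype=np.float64)

    def __repr__(self) -> str:  # pragma: no cover
        return f"FeatureVector({len(self)} features)"


@dataclass
class SampleTable:
    """Cohort table: one row per sample, the 40 features plus ``age``.

    ``data`` is a DataFrame indexed by unique sample id with columns
    ``FEATURE_NAMES + ('age',)`` and optionally ``'group'``.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        required = list(FEATURE_NAMES) + ["age"]
        missing = [c for c in required if c not in df.columns]
        extra = [c for c in df.columns if c not in required + ["group"]]
        if missing or extra:
            raise SchemaError(
                f"sample table columns mismatch: missing={missing}, extra={extra}"
            )
        if not df.index.is_unique:
            raise ValueError("sample ids must be unique")
        if len(df):
            feats = df[list(FEATURE_NAMES)]
            if feats.isna().any().any():
                bad = feats.columns[feats.isna().any()].tolist()
                raise ValueError(f"missing feature values in columns {bad}")
            if (df["age"] <= 0).any():
                raise ValueError("ages must be positive")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def features(self) -> pd.DataFrame:
        return self.data[list(FEATURE_NAMES)]

    @property
    def ages(self) -> pd.Series:
        return self.data["age"]

    @classmethod
    def from_rows(
        cls,
        sample_ids: Sequence[str],
        features: Sequence[FeatureVector],
        ages: Sequence[float],
        groups: Sequence[str] | None = None,
    ) -> "SampleTable":
        df = pd.DataFrame(
            [fv.as_series() for fv in features],
            index=pd.Index(sample_ids, name="sample_id"),
        )
        df["age"] = np.asarray(ages, dtype=np.float64)
        if groups is not None:
            df["group"] = list(groups)
        return cls(df)


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

_SPACING_KEY = "vesselmink_spacing_um"


def _read_pages(path) -> np.ndarray:
    try:
        with tifffile.TiffFile(str(path)) as tf:
            pages = [p.asarray() for p in tf.pages]
            meta = tf.shaped_metadata or tf.imagej_metadata or None
    except (FileNotFoundError, OSError, tifffile.TiffFileError) as exc:
        raise FormatError(f"cannot read TIFF {path!r}: {exc}") from exc
    if len(pages) < 2:
        raise FormatError(f"{path!r}: a z-stack needs >= 2 pages, got {len(pages)}")
    shape0 = pages[0].shape
    for i, p in enumerate(pages):
        if p.ndim != 2:
            raise FormatError(f"{path!r}: page {i} is not grayscale 2D (shape {p.shape})")
        if p.shape != shape0:
            raise FormatError(
                f"{path!r}: page {i} shape {p.shape} differs from page 0 {shape0}"
            )
    return np.stack(pages, axis=0), meta


def _spacing_from_meta(meta) -> tuple[float, float, float] | None:
    if not meta:
        return None
    entries = meta if isinstance(meta, (list, tuple)) else [meta]
    for entry in entries:
        if isinstance(entry, dict) and _SPACING_KEY in entry:
            return _check_spacing(entry[_SPACING_KEY])
    return None


def read_zstack(path, spacing=None) -> ZStack:
    """Read a multi-page grayscale TIFF into a :class:`ZStack`.

    Spacing resolution order: embedded metadata, then the ``spacing`` argument,
    then ``(1, 1, 1)`` voxel units.
    """
    voxels, meta = _read_pages(path)
    sp = _spacing_from_meta(meta) or (spacing and _check_spacing(spacing)) or (1.0, 1.0, 1.0)
    if not np.issubdtype(voxels.dtype, np.number):
        raise FormatError(f"{path!r}: non-numeric pixel type {voxels.dtype}")
    return ZStack(voxels=np.asarray(voxels, dtype=np.float64), spacing=sp,
                  meta={"path": str(path)})


def read_binary_volume(path) -> BinaryVolume:
    """Read a 0/255 (or 0/1) multi-page TIFF into a :class:`BinaryVolume`."""
    voxels, meta = _read_pages(path)
    sp = _spacing_from_meta(meta) or (1.0, 1.0, 1.0)
    return BinaryVolume(occupancy=voxels > 0, spacing=sp, meta={"path": str(path)})


def read_thickness_map(path) -> ThicknessMap:
    voxels, meta = _read_pages(path)
    sp = _spacing_from_meta(meta) or (1.0, 1.0, 1.0)
    return ThicknessMap(diameters=np.asarray(voxels, dtype=np.float64), spacing=sp)


def write_volume(vol, path) -> None:
    """Write a ZStack / BinaryVolume / ThicknessMap as a multi-page TIFF.

    Binary volumes are stored as uint8 0/255; spacing is recorded in the shaped
    metadata so reads round-trip.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"parent directory does not exist: {path.parent}")
    if isinstance(vol, BinaryVolume):
        data = (vol.occupancy.astype(np.uint8)) * 255
        sp = vol.spacing
    elif isinstance(vol, ThicknessMap):
        data = vol.diameters.astype(np.float32)
        sp = vol.spacing
    elif isinstance(vol, ZStack):
        data = vol.voxels
        if np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float32)
        sp = vol.spacing
    else:
        raise TypeError(f"cannot write object of type {type(vol).__name__}")
    tifffile.imwrite(str(path), data, photometric="minisblack",
                     metadata={_SPACING_KEY: list(sp)})


# ---------------------------------------------------------------------------
# Feature-table I/O
# ---------------------------------------------------------------------------


def read_feature_table(path) -> SampleTable:
    """Read a cohort CSV (sample_id, 40 features, age[, group])."""
    df = pd.read_csv(path)
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    extra = [
        c for c in df.columns if c not in list(FEATURE_NAMES) + ["age", "group"]
    ]
    if missing or extra:
        raise SchemaError(
            f"{path!r}: feature columns mismatch: missing={missing}, extra={extra}"
        )
    if "age" not in df.columns:
        raise SchemaError(f"{path!r}: missing required column 'age'")
    df["age"] = df["age"].astype(np.float64)
    return SampleTable(df)


def write_feature_table(table: SampleTable, path) -> None:
    table.data.to_csv(path, index_label="sample_id")


# ---------------------------------------------------------------------------
# Config and logging
# ---------------------------------------------------------------------------


def read_config(path) -> dict:
    """Read a run configuration: JSON, or plain-text ``key=value`` lines."""
    text = Path(path).read_text()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        return json.loads(text)
    cfg: dict = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"{path!r}:{lineno}: expected key=value, got {line!r}")
        key, _, value = line.partition("=")
        try:
            cfg[key.strip()] = json.loads(value.strip())
        except json.JSONDecodeError:
            cfg[key.strip()] = value.strip()
    return cfg


def get_logger() -> logging.Logger:
    """Package logger, writing structured stage messages to stderr."""
    if not log.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        log.addHandler(handler)
        log.setLevel(logging.INFO)
    return log


class stage_timer:
    """Context manager logging wall time of a pipeline stage."""

    def __init__(self, stage: str):
        self.stage = stage

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        dt = time.perf_counter() - self.t0
        get_logger().info("stage=%s elapsed=%.3fs", self.stage, dt)
        return False


def write_sidecar(path, payload: dict) -> None:
    """Write a JSON provenance sidecar next to an artifact."""
    side = Path(str(path) + ".json")

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)

    side.write_text(json.dumps(payload, indent=2, default=_default))
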