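"""Domain types, voxel geometry and NIfTI I/O shared by every pipeline stage.

A *case* consists of four co-registered, skull-stripped MR volumes (T1w,
T1w-gadolinium, T2w, FLAIR) on one voxel grid, plus one or more binary
resection-cavity label maps on the same grid.  All stages operate on the
types below; files are NIfTI (.nii / .nii.gz) read and written with nibabel.
"""

from __future__ import annotations

import re
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "SEQUENCES",
    "Geometry",
    "ImageVolume",
    "MultimodalStudy",
    "LabelMap",
    "ProbabilityMap",
    "ConfigurationError",
    "ConformanceError",
    "DegenerateInputError",
    "load_volume",
    "load_study",
    "load_labelmap",
    "write_labelmap",
    "write_volume",
    "volume_cm3",
    "read_case_manifest",
    "write_case_manifest",
    "read_cohort_manifest",
    "write_cohort_manifest",
]

#: canonical sequence names, in channel order fed to the network
SEQUENCES = ("t1", "t1gad", "t2", "flair")

#: absolute tolerance (mm) for all geometry comparisons
GEOMETRY_ATOL = 1e-3

#: values within this distance of 0 or 1 are rounded when loading label maps
LABEL_TOL = 1e-3


class ConfigurationError(ValueError):
    """Invalid or incomplete configuration (missing sequence, bad option)."""


class ConformanceError(ValueError):
    """Volumes that must share a grid do not."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but carries no usable signal."""


@dataclass(frozen=True)
class Geometry:
    """Voxel grid geometry: shape, spacing (mm) and the NIfTI affine."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"grid must be 3D with >=1 voxel per axis, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "affine", aff)

    def matches(self, other: "Geometry", atol: float = GEOMETRY_ATOL) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.affine, other.affine, atol=atol)
        )

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


def _require_same_grid(geoms: Mapping[str, Geometry]) -> None:
    names = list(geoms)
    ref = geoms[names[0]]
    bad = [n for n in names[1:] if not geoms[n].matches(ref)]
    if bad:
        desc = "; ".join(
            f"{n}: shape={geoms[n].shape}, spacing={tuple(round(s, 4) for s in geoms[n].spacing)}"
            for n in names
        )
        raise ConformanceError(f"volumes are not on a common grid ({desc})")


@dataclass
class ImageVolume:
    """One scalar MR volume (arbitrary intensity units) with its geometry."""

    values: np.ndarray
    geometry: Geometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.values.ndim}")
        if self.values.shape != self.geometry.shape:
            raise ConformanceError(
                f"value array shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")


@dataclass
class MultimodalStudy:
    """Four co-registered MR volumes of one case, on one voxel grid."""

    case_id: str
    t1: ImageVolume
    t1gad: ImageVolume
    t2: ImageVolume
    flair: ImageVolume

    def __post_init__(self) -> None:
        _require_same_grid({name: getattr(self, name).geometry for name in SEQUENCES})

    @property
    def geometry(self) -> Geometry:
        return self.t1.geometry

    def channels(self) -> np.ndarray:
        """Stack the four sequences as a (4, X, Y, Z) array in canonical order."""
        return np.stack([getattr(self, name).values for name in SEQUENCES])

    @classmethod
    def from_channels(cls, case_id: str, channels: np.ndarray, geometry: Geometry) -> "MultimodalStudy":
        vols = {name: ImageVolume(channels[i], geometry) for i, name in enumerate(SEQUENCES)}
        return cls(case_id=case_id, **vols)


@dataclass
class LabelMap:
    """Binary 3D mask (resection cavity vs background) on a study grid."""

    values: np.ndarray
    geometry: Geometry

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={vals.ndim}")
        uniq = np.unique(vals)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"label map must be binary, found values {uniq[:10]}")
        self.values = vals.astype(np.uint8)
        if self.values.shape != self.geometry.shape:
            raise ConformanceError(
                f"mask shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )

    @property
    def num_foreground(self) -> int:
        return int(self.values.sum())


@dataclass
class ProbabilityMap:
    """Per-voxel foreground probability volume."""

    values: np.ndarray
    geometry: Geometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.geometry.shape:
            raise ConformanceError(
                f"probability shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("probabilities must lie in [0, 1]")
        np.clip(self.values, 0.0, 1.0, out=self.values)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _geometry_of(img: nib.Nifti1Image) -> Geometry:
    shape = tuple(int(s) for s in img.shape[:3])
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Geometry(shape=shape, spacing=spacing, affine=np.asarray(img.affine, dtype=float))


def load_volume(path: str | Path) -> ImageVolume:
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=np.float64)
    if values.ndim == 4 and values.shape[3] == 1:
        values = values[..., 0]
    return ImageVolume(values=values, geometry=_geometry_of(img))


def load_study(paths: Mapping[str, str | Path], case_id: str | None = None) -> MultimodalStudy:
    """Load the four sequences of one case and verify grid conformance.

    ``paths`` maps sequence names (``t1``, ``t1gad``, ``t2``, ``flair``) to
    NIfTI files.  Raises :class:`ConfigurationError` if a sequence is missing
    and :class:`ConformanceError` if the grids differ.
    """
    missing = [name for name in SEQUENCES if name not in paths]
    if missing:
        raise ConfigurationError(f"missing sequence path(s): {', '.join(missing)}")
    vols = {name: load_volume(paths[name]) for name in SEQUENCES}
    _require_same_grid({name: v.geometry for name, v in vols.items()})
    cid = case_id if case_id is not None else Path(str(paths["t1"])).parent.name or "case"
    return MultimodalStudy(case_id=cid, **vols)


def load_labelmap(path: str | Path, reference: MultimodalStudy | Geometry) -> LabelMap:
    """Load a binary mask and check it lives on the reference grid.

    Float dialects are tolerated: values within ``1e-3`` of 0 or 1 are
    rounded; anything else (e.g. an interpolated mask) is a ``ValueError``.
    """
    geom = reference.geometry if isinstance(reference, MultimodalStudy) else reference
    img = nib.load(str(path))
    file_geom = _geometry_of(img)
    if not file_geom.matches(geom):
        raise ConformanceError(
            f"mask grid (shape={file_geom.shape}, spacing={file_geom.spacing}) does not "
            f"match reference grid (shape={geom.shape}, spacing={geom.spacing})"
        )
    raw = np.asarray(img.dataobj, dtype=np.float64)
    rounded = np.rint(raw)
    if np.any(np.abs(raw - rounded) > LABEL_TOL) or not np.all(np.isin(np.unique(rounded), (0, 1))):
        bad = np.unique(raw[np.abs(raw - np.rint(raw)) > LABEL_TOL])
        offender = bad[0] if bad.size else np.unique(rounded)
        raise ValueError(f"label map is not binary within tolerance (found {offender})")
    return LabelMap(values=rounded.astype(np.uint8), geometry=geom)


def write_labelmap(mask: LabelMap, path: str | Path) -> None:
    """Write a mask so that a round-trip load is voxel- and affine-identical."""
    img = nib.Nifti1Image(mask.values.astype(np.uint8), mask.geometry.affine)
    img.header.set_zooms(mask.geometry.spacing)
    nib.save(img, str(path))


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float32), volume.geometry.affine)
    img.header.set_zooms(volume.geometry.spacing)
    nib.save(img, str(path))


def volume_cm3(mask: LabelMap) -> float:
    """Absolute foreground volume in cm³ (voxel count × voxel volume)."""
    return mask.num_foreground * mask.geometry.voxel_volume_mm3 / 1000.0


# ---------------------------------------------------------------------------
# Manifests: plain-text "key: path" tables
# ---------------------------------------------------------------------------

_MANIFEST_LINE = re.compile(r"^\s*([^:#\s][^:]*?)\s*:\s*(.+?)\s*$")


def read_case_manifest(path: str | Path) -> "OrderedDict[str, Path]":
    """Parse a per-case manifest mapping keys (sequences, raters) to paths.

    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    entries: OrderedDict[str, Path] = OrderedDict()
    for line in path.read_text().splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        m = _MANIFEST_LINE.match(line)
        if not m:
            raise ConfigurationError(f"malformed manifest line in {path}: {line!r}")
        key, value = m.group(1), m.group(2)
        p = Path(value)
        entries[key] = p if p.is_absolute() else (path.parent / p)
    return entries


def write_case_manifest(entries: Mapping[str, str | Path], path: str | Path) -> None:
    path = Path(path)
    lines = [f"{k}: {v}" for k, v in entries.items()]
    path.write_text("\n".join(lines) + "\n")


def read_cohort_manifest(path: str | Path) -> "OrderedDict[str, Path]":
    """Parse a cohort index mapping case ids to per-case manifest paths."""
    return read_case_manifest(path)


def write_cohort_manifest(entries: Mapping[str, str | Path], path: str | Path) -> None:
    write_case_manifest(entries, path)
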