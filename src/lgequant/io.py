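"""Readers/writers and run configuration.

World coordinates follow the DICOM LPS convention; ``origin`` always
refers to the *center* of the first voxel/pixel (half-voxel convention).
NIfTI affines (which map indices to RAS) are converted on the fly.
Supported inputs: NIfTI-1 volumes, directories of single-frame DICOM
files, JSON slice-geometry sidecars and JSON polygon contour files.
Numeric outputs embed a provenance block (config hash, seed, software
version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
import yaml
from shapely.geometry import Polygon

from . import __version__
from .errors import ConfigError, IoError
from .geometry import SliceGeometry, VolumeGrid
from .quantify import ContourSet, SliceContours

__all__ = [
    "read_volume",
    "write_volume",
    "read_slice_geometries",
    "write_slice_geometries",
    "read_contours",
    "write_contours",
    "RunConfig",
    "provenance_block",
    "write_json",
]

_LPS_FROM_RAS = np.diag([-1.0, -1.0, 1.0])


# --------------------------------------------------------------------- NIfTI
def _volume_from_affine(voxels: np.ndarray, affine_lps: np.ndarray) -> VolumeGrid:
    m = affine_lps[:3, :3]
    spacing = np.linalg.norm(m, axis=0)
    if np.any(spacing <= 0):
        raise IoError("affine has a zero-length column")
    axes = (m / spacing).T  # rows = direction cosines of index axes
    gram = axes @ axes.T
    dev = np.abs(gram - np.eye(3)).max()
    if dev > 1e-4:
        raise IoError(
            "volume affine is not orthonormal (shear or non-orthogonal axes); "
            f"max Gram deviation {dev:.3e} — reslicing assumes a rigid lattice"
        )
    # re-orthonormalize exactly to pass strict geometry checks
    u, _, vt = np.linalg.svd(axes)
    axes = u @ vt
    return VolumeGrid(voxels, affine_lps[:3, 3], axes, spacing)


def read_volume(path: str | Path) -> VolumeGrid:
    """Read a 3D volume from a NIfTI file or a single-frame DICOM directory."""
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise IoError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise IoError(f"expected a 3D volume, got shape {data.shape}")
    affine_ras = img.affine
    affine_lps = np.eye(4)
    affine_lps[:3, :3] = _LPS_FROM_RAS @ affine_ras[:3, :3]
    affine_lps[:3, 3] = _LPS_FROM_RAS @ affine_ras[:3, 3]
    return _volume_from_affine(data, affine_lps)


def write_volume(volume: VolumeGrid, path: str | Path) -> None:
    """Write a VolumeGrid as NIfTI-1 (LPS geometry converted to RAS affine)."""
    m = (volume.axes * volume.spacing[:, None]).T  # columns = index axes
    affine_ras = np.eye(4)
    affine_ras[:3, :3] = _LPS_FROM_RAS @ m
    affine_ras[:3, 3] = _LPS_FROM_RAS @ volume.origin
    nib.save(nib.Nifti1Image(volume.voxels, affine_ras), str(path))


def _read_dicom_series(path: Path) -> VolumeGrid:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ".ima", ""))
    datasets = []
    for f in files:
        if f.is_dir():
            continue
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:
            continue
    if not datasets:
        raise IoError(f"no readable DICOM files in {path}")
    try:
        iop = np.asarray(datasets[0].ImageOrientationPatient, dtype=float)
        ps = np.asarray(datasets[0].PixelSpacing, dtype=float)
    except AttributeError as exc:
        raise IoError(f"missing geometry tags in DICOM series: {exc}") from exc
    for ds in datasets[1:]:
        if not np.allclose(np.asarray(ds.ImageOrientationPatient, dtype=float), iop):
            raise IoError("non-uniform ImageOrientationPatient across the series")
        if not np.allclose(np.asarray(ds.PixelSpacing, dtype=float), ps):
            raise IoError("non-uniform PixelSpacing across the series")
    row_dir, col_dir = iop[:3], iop[3:]
    normal = np.cross(row_dir, col_dir)
    datasets.sort(key=lambda ds: float(np.dot(ds.ImagePositionPatient, normal)))
    positions = np.array([np.dot(ds.ImagePositionPatient, normal) for ds in datasets])
    if len(datasets) < 2:
        raise IoError("need at least two slices to infer slice spacing")
    gaps = np.diff(positions)
    if gaps.min() <= 0:
        raise IoError("duplicate slice positions in DICOM series")
    if not np.allclose(gaps, gaps[0], atol=1e-3):
        raise IoError(
            "inconsistent inter-slice spacing in DICOM series (missing slice?): "
            f"gaps range {gaps.min():.4g}..{gaps.max():.4g} mm"
        )
    voxels = np.stack([ds.pixel_array.astype(float) for ds in datasets])  # (k, r, c)
    axes = np.vstack([normal, col_dir, row_dir])
    spacing = np.array([gaps[0], ps[0], ps[1]])
    origin = np.asarray(datasets[0].ImagePositionPatient, dtype=float)
    return VolumeGrid(voxels, origin, axes, spacing)


# ------------------------------------------------------- slice geometries
def write_slice_geometries(geoms: list[SliceGeometry], path: str | Path) -> None:
    records = [
        {
            "origin": g.origin.tolist(),
            "row_dir": g.row_dir.tolist(),
            "col_dir": g.col_dir.tolist(),
            "pixel_spacing": g.pixel_spacing.tolist(),
            "n_rows": int(g.n_rows),
            "n_cols": int(g.n_cols),
            "thickness": float(g.thickness),
        }
        for g in geoms
    ]
    Path(path).write_text(json.dumps({"slices": records}, indent=1))


def read_slice_geometries(path: str | Path) -> list[SliceGeometry]:
    try:
        payload = json.loads(Path(path).read_text())
        return [SliceGeometry(**{**r, "origin": np.asarray(r["origin"])}) for r in payload["slices"]]
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise IoError(f"malformed slice-geometry sidecar {path}: {exc}") from exc


# ----------------------------------------------------------------- contours
def _poly_coords(poly: Polygon) -> list:
    return [[float(x), float(y)] for x, y in np.asarray(poly.exterior.coords)[:-1]]


def write_contours(contours: ContourSet, path: str | Path) -> None:
    records = []
    for ctr in contours:
        records.append(
            {
                "slice_index": ctr.slice_index,
                "endo": _poly_coords(ctr.endo),
                "epi": _poly_coords(ctr.epi),
                "rois": {role: _poly_coords(p) for role, p in ctr.rois.items()},
            }
        )
    Path(path).write_text(json.dumps({"slices": records}, indent=1))


def read_contours(path: str | Path) -> ContourSet:
    try:
        payload = json.loads(Path(path).read_text())
        slices = [
            SliceContours(
                slice_index=int(r["slice_index"]),
                endo=Polygon(r["endo"]),
                epi=Polygon(r["epi"]),
                rois={role: Polygon(c) for role, c in r.get("rois", {}).items()},
            )
            for r in payload["slices"]
        ]
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise IoError(f"malformed contour file {path}: {exc}") from exc
    return ContourSet(slices)


# ------------------------------------------------------------ configuration
@dataclass
class RunConfig:
    """Configuration of one pipeline run; fully serialized into provenance.

    Convention-level parameters are surfaced here with their defaults:
    ``span_rule`` (slab plane-count rule), ``density`` (1.05 g/ml) and
    ``nsd_n`` (3 SD); inclusive thresholding and basal tie-breaks are
    fixed conventions documented in the methods note.
    """

    out_dir: str
    pattern: str = "ischemic"  # ischemic | myocarditis
    method: str = "auto"  # auto | fwhm | nsd
    snr: float = 20.0
    seed: int = 0
    nsd_n: float = 3.0
    density: float = 1.05
    span_rule: str = "ceil"
    noise: bool = True
    oblique_deg: tuple[float, float, float] = (12.0, 8.0, 20.0)

    def __post_init__(self) -> None:
        if self.pattern not in ("ischemic", "myocarditis"):
            raise ConfigError(f"unknown pattern {self.pattern!r}")
        if self.method not in ("auto", "fwhm", "nsd"):
            raise ConfigError(f"unknown method {self.method!r}")
        if self.span_rule not in ("ceil", "floor"):
            raise ConfigError(f"unknown span rule {self.span_rule!r}")
        if self.density <= 0 or self.snr <= 0:
            raise ConfigError("density and snr must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        payload.update(overrides)
        try:
            return cls(**payload)
        except TypeError as exc:
            raise ConfigError(f"invalid config {path}: {exc}") from exc

    def to_dict(self) -> dict:
        d = asdict(self)
        d["oblique_deg"] = list(self.oblique_deg)
        return d

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def provenance_block(config: RunConfig | None = None, seed: int | None = None) -> dict:
    block = {"software": "lgequant", "version": __version__}
    if config is not None:
        block["config_hash"] = config.config_hash
        block["config"] = config.to_dict()
        block["seed"] = config.seed
    if seed is not None:
        block["seed"] = seed
    return block


def write_json(payload: dict, path: str | Path, provenance: dict | None = None) -> None:
    """Write a JSON result file with an embedded provenance block."""
    doc = dict(payload)
    if provenance is not None:
        doc["provenance"] = provenance

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(doc, indent=1, default=_default))
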