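"""Synthetic left-ventricle LGE phantom with ground truth.

The left ventricle is modelled as a truncated half-ellipsoid shell: the
epicardial and endocardial surfaces are confocal-style ellipsoids centred
on the base plane (z = 0), kept for z >= 0, apex toward z = +L (L = the
epicardial long semi-axis).  The blood pool fills the endocardial cavity.
Two hyperenhancement patterns emulate the study phenotypes:

* ``ischemic`` — a subendocardial wedge (infarct): an angular sector,
  limited axial span, scar occupying the inner ``transmurality`` fraction
  of the wall, signal close to the blood pool (FWHM regime).
* ``myocarditis`` — a subepicardial band on the basal inferior/lateral
  wall, scar occupying the outer ``transmurality`` fraction of the wall,
  modest signal elevation above remote myocardium (mean+3SD regime).

Optional small ellipsoidal papillary lesions are attached to the
endocardial surface inside the blood pool.  Signal is piecewise constant
per tissue; acquisition simulates partial volume by averaging the analytic
signal over a ~0.25 mm sub-voxel lattice, then adds Rician noise
(magnitude MRI): ``|SI + n1 + i n2|`` with ``n1, n2 ~ N(0, sigma)``,
``sigma = SI_myo / SNR``.  Identical (spec, seed) reproduce bit-identical
volumes.

Ground truth is evaluated on a fine 0.25 mm lattice: label volume
(background / blood / myocardium / scar / papillary), true masses at
1.05 g/ml, true LGE extent, and per-segment extents.  Papillary lesions
are excluded from myocardial mass and extent, mirroring visual (not
quantitative) papillary scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidParameterError
from .geometry import PlanarImage, SliceGeometry, VolumeGrid
from .quantify import MYOCARDIAL_DENSITY_G_PER_ML

__all__ = [
    "ScarPattern",
    "PapillaryLesion",
    "PhantomSpec",
    "PhantomTruth",
    "AnalyticPhantom",
    "build_phantom",
    "acquire_isotropic",
    "sax_geometries",
    "acquire_sax",
    "analytic_contours",
    "rv_insertion_points",
]

LABEL_BACKGROUND, LABEL_BLOOD, LABEL_MYO, LABEL_SCAR, LABEL_PAPILLARY = range(5)
FINE_SPACING_MM = 0.25
_SUB_SPACING_MM = 0.25  # target sub-voxel averaging pitch for partial volume


@dataclass(frozen=True)
class ScarPattern:
    """Angular-sector scar region within the myocardial shell."""

    kind: str  # 'ischemic' (subendocardial) or 'myocarditis' (subepicardial)
    center_angle_deg: float
    angular_extent_deg: float
    z_span_frac: tuple[float, float]  # fraction of base->apex length
    transmurality: float  # fraction of wall thickness, (0, 1]
    # myocarditis only: preserved epicardial rim (fraction of wall thickness)
    # between the enhancement band and the epicardial surface, as in
    # outer-wall/mid-wall inflammatory enhancement
    epicardial_rim_frac: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in ("ischemic", "myocarditis"):
            raise InvalidParameterError(f"unknown scar kind {self.kind!r}")
        if not (0 < self.transmurality <= 1):
            raise InvalidParameterError("transmurality must be in (0, 1]")
        z0, z1 = self.z_span_frac
        if not (0 <= z0 < z1 <= 1):
            raise InvalidParameterError("z_span_frac must satisfy 0 <= z0 < z1 <= 1")
        if not (0 < self.angular_extent_deg <= 360):
            raise InvalidParameterError("angular_extent_deg must be in (0, 360]")


@dataclass(frozen=True)
class PapillaryLesion:
    """Small hyperenhanced ellipsoid attached to the endocardial surface."""

    azimuth_deg: float
    z_frac: float  # fraction of base->apex length
    radii: tuple[float, float, float]  # mm


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic LV acquisition target.

    Default geometry: epicardial semi-axes (35, 35, 80) mm, endocardial
    (27, 27, 72) mm — a ~95 ml myocardial shell (~100 g).  Default signal
    levels: blood pool 440, remote myocardium 100 (contrast ratio 0.77),
    ischemic scar 440 (scar approaches blood), myocarditis scar 125 (low
    contrast).  SNR = remote SI / sigma, default 20; ``math.inf`` disables
    noise.
    """

    epi_semi_axes: tuple[float, float, float] = (35.0, 35.0, 80.0)
    endo_semi_axes: tuple[float, float, float] = (27.0, 27.0, 72.0)
    scar: ScarPattern = field(
        default_factory=lambda: ScarPattern(
            "ischemic", 250.0, 100.0, (0.05, 0.60), 0.65
        )
    )
    papillary: tuple[PapillaryLesion, ...] = ()
    si_blood: float = 440.0
    si_myo: float = 100.0
    si_scar: float = 440.0
    snr: float = 20.0
    rv_insertion_angle_deg: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        epi = np.asarray(self.epi_semi_axes, dtype=float)
        endo = np.asarray(self.endo_semi_axes, dtype=float)
        if np.any(endo >= epi):
            raise InvalidParameterError(
                "endocardial semi-axes must be strictly smaller than epicardial"
            )
        if np.any(epi <= 0):
            raise InvalidParameterError("semi-axes must be positive")
        if self.si_scar <= self.si_myo:
            raise InvalidParameterError("scar SI must exceed remote myocardial SI")
        if self.snr <= 0:
            raise InvalidParameterError("snr must be positive (math.inf = noiseless)")

    @property
    def noise_sigma(self) -> float:
        return 0.0 if math.isinf(self.snr) else self.si_myo / self.snr

    @property
    def length(self) -> float:
        """Base-to-apex length (mm)."""
        return float(self.epi_semi_axes[2])

    @classmethod
    def ischemic(cls, seed: int = 0, snr: float = 20.0, **overrides) -> "PhantomSpec":
        """Chronic-infarct phenotype: bright subendocardial inferolateral wedge."""
        return cls(seed=seed, snr=snr, **overrides)

    @classmethod
    def myocarditis(cls, seed: int = 0, snr: float = 20.0, **overrides) -> "PhantomSpec":
        """Myocarditis phenotype: basal inferior/lateral outer-wall band.

        The enhancement is parameterised by its contrast-to-noise ratio:
        scar SI sits 5 noise SDs above remote myocardium (125 at the
        default SNR 20), the regime the mean+3SD method is designed for.
        For a noiseless spec the +5 sigma rule has no scale and the SNR-20
        level is kept.
        """
        si_myo = overrides.get("si_myo", 100.0)
        cnr_sigma = si_myo / (snr if math.isfinite(snr) else 20.0)
        defaults = dict(
            scar=ScarPattern("myocarditis", 230.0, 160.0, (0.02, 0.55), 0.50),
            si_scar=si_myo + 5.0 * cnr_sigma,
        )
        defaults.update(overrides)
        return cls(seed=seed, snr=snr, **defaults)

    def with_(self, **overrides) -> "PhantomSpec":
        return replace(self, **overrides)


def _angular_distance_deg(angle: np.ndarray, center: float) -> np.ndarray:
    d = np.mod(angle - center + 180.0, 360.0) - 180.0
    return np.abs(d)


class AnalyticPhantom:
    """Point-wise analytic evaluation of tissue label and signal."""

    SI_LUT_INDEX = (LABEL_BACKGROUND, LABEL_BLOOD, LABEL_MYO, LABEL_SCAR, LABEL_PAPILLARY)

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        self._si_lut = np.array(
            [0.0, spec.si_blood, spec.si_myo, spec.si_scar, spec.si_scar]
        )

    def label(self, points: np.ndarray) -> np.ndarray:
        """Tissue label (uint8) at world points of shape (..., 3)."""
        spec = self.spec
        p = np.asarray(points, dtype=float)
        x, y, z = p[..., 0], p[..., 1], p[..., 2]
        a, b, c = spec.epi_semi_axes
        ae, be, ce = spec.endo_semi_axes
        u_epi = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2
        u_endo = (x / ae) ** 2 + (y / be) ** 2 + (z / ce) ** 2
        half = z >= 0.0
        blood = half & (u_endo <= 1.0)
        myo = half & (u_epi <= 1.0) & (u_endo > 1.0)

        lab = np.zeros(p.shape[:-1], dtype=np.uint8)
        lab[blood] = LABEL_BLOOD
        lab[myo] = LABEL_MYO

        # wall coordinate: 0 at the epicardial surface, 1 at the endocardial
        with np.errstate(divide="ignore", invalid="ignore"):
            m_endo = np.sqrt(u_endo)
            m_epi = np.sqrt(u_epi)
            nu = (1.0 - m_epi) / np.maximum(m_endo - m_epi, 1e-12)
        sc = self.spec.scar
        phi = np.degrees(np.arctan2(y, x)) % 360.0
        in_wedge = _angular_distance_deg(phi, sc.center_angle_deg) <= sc.angular_extent_deg / 2.0
        zf = z / spec.length
        in_span = (zf >= sc.z_span_frac[0]) & (zf <= sc.z_span_frac[1])
        if sc.kind == "ischemic":
            depth_ok = nu >= 1.0 - sc.transmurality  # endocardial side
        else:
            # outer-wall band: spared epicardial rim, then the scar band
            lo = sc.epicardial_rim_frac
            depth_ok = (nu >= lo) & (nu <= min(1.0, lo + sc.transmurality))
        lab[myo & in_wedge & in_span & depth_ok] = LABEL_SCAR

        for les in spec.papillary:
            zl = les.z_frac * spec.length
            k = math.sqrt(max(0.0, 1.0 - (zl / ce) ** 2)) * 0.85
            phi_l = math.radians(les.azimuth_deg)
            cx, cy = ae * k * math.cos(phi_l), be * k * math.sin(phi_l)
            rx, ry, rz = les.radii
            u = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - zl) / rz) ** 2
            lab[blood & (u <= 1.0)] = LABEL_PAPILLARY
        return lab

    def si(self, points: np.ndarray) -> np.ndarray:
        """Noiseless signal intensity at world points (piecewise constant)."""
        return self._si_lut[self.label(points)]

    # --- ellipse cross sections (used for contour generation) -------------
    def endo_axes_at(self, z: float) -> tuple[float, float] | None:
        ae, be, ce = self.spec.endo_semi_axes
        if z < 0 or z >= ce:
            return None
        k = math.sqrt(1.0 - (z / ce) ** 2)
        return ae * k, be * k

    def epi_axes_at(self, z: float) -> tuple[float, float] | None:
        a, b, c = self.spec.epi_semi_axes
        if z < 0 or z >= c:
            return None
        k = math.sqrt(1.0 - (z / c) ** 2)
        return a * k, b * k


@dataclass
class PhantomTruth:
    """Fine-lattice ground truth of one phantom."""

    spec: PhantomSpec
    labels: np.ndarray  # uint8, shape (nx, ny, nz)
    x: np.ndarray  # fine-voxel center coordinates, mm
    y: np.ndarray
    z: np.ndarray
    spacing: float
    density: float
    myo_mass: float  # g, scar included, papillary excluded
    scar_mass: float  # g
    extent: float  # %
    volumes_ml: dict

    def masses_in_slab(self, z_low: float, z_high: float) -> dict:
        """Truth masses (g) restricted to fine voxels with z in [z_low, z_high)."""
        sel = (self.z >= z_low) & (self.z < z_high)
        lab = self.labels[:, :, sel]
        voxel_ml = self.spacing**3 / 1000.0
        myo_ml = float(np.sum((lab == LABEL_MYO) | (lab == LABEL_SCAR))) * voxel_ml
        scar_ml = float(np.sum(lab == LABEL_SCAR)) * voxel_ml
        myo_g = myo_ml * self.density
        scar_g = scar_ml * self.density
        extent = 100.0 * scar_g / myo_g if myo_g > 0 else float("nan")
        return {"myo_mass_g": myo_g, "scar_mass_g": scar_g, "extent_pct": extent}

    def segment_extents(
        self,
        slice_edges: list[tuple[float, float]],
        insertion_angle_deg: float | None = None,
        clockwise: bool = False,
    ) -> np.ndarray:
        """True per-segment LGE extent (%) for a given slice partition.

        ``slice_edges`` lists (z_low, z_high) per slice, base -> apex; the
        slices are grouped into basal/mid/apical thirds exactly as the
        segment-mapping module does.
        """
        from .aha import split_levels, _LEVEL_LAYOUT

        if insertion_angle_deg is None:
            insertion_angle_deg = self.spec.rv_insertion_angle_deg
        chi = -1.0 if clockwise else 1.0
        levels = split_levels(len(slice_edges))
        xx, yy = np.meshgrid(self.x, self.y, indexing="ij")
        phi = np.degrees(np.arctan2(yy, xx))
        myo_cnt = np.zeros(17)
        scar_cnt = np.zeros(17)
        for (z0, z1), level in zip(slice_edges, levels):
            first_id, width = _LEVEL_LAYOUT[level]
            n_sectors = int(round(360.0 / width))
            sel = (self.z >= z0) & (self.z < z1)
            lab = self.labels[:, :, sel]
            rel = np.mod(chi * (phi - insertion_angle_deg), 360.0)
            sector = np.minimum((rel // width).astype(int), n_sectors - 1)
            seg = first_id + sector  # (nx, ny)
            myo3 = (lab == LABEL_MYO) | (lab == LABEL_SCAR)
            scar3 = lab == LABEL_SCAR
            myo_cnt += np.bincount(
                np.broadcast_to(seg[:, :, None], lab.shape)[myo3], minlength=17
            )
            scar_cnt += np.bincount(
                np.broadcast_to(seg[:, :, None], lab.shape)[scar3], minlength=17
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            ext = np.where(myo_cnt > 0, 100.0 * scar_cnt / np.maximum(myo_cnt, 1), 0.0)
        return ext[1:17]


def build_phantom(
    spec: PhantomSpec,
    lattice_spacing: float = FINE_SPACING_MM,
    density: float = MYOCARDIAL_DENSITY_G_PER_ML,
) -> tuple[PhantomTruth, AnalyticPhantom]:
    """Evaluate the analytic phantom on a fine lattice and compute truth masses."""
    phantom = AnalyticPhantom(spec)
    a, b, _ = spec.epi_semi_axes
    h = lattice_spacing
    x = np.arange(-(a + 1.0), a + 1.0 + h / 2, h)
    y = np.arange(-(b + 1.0), b + 1.0 + h / 2, h)
    z = np.arange(h / 2, spec.length + h / 2, h)
    labels = np.empty((x.size, y.size, z.size), dtype=np.uint8)
    chunk = max(1, int(2_000_000 / (x.size * y.size)))
    xx, yy = np.meshgrid(x, y, indexing="ij")
    for k0 in range(0, z.size, chunk):
        zz = z[k0 : k0 + chunk]
        pts = np.empty((x.size, y.size, zz.size, 3))
        pts[..., 0] = xx[:, :, None]
        pts[..., 1] = yy[:, :, None]
        pts[..., 2] = zz[None, None, :]
        labels[:, :, k0 : k0 + chunk] = phantom.label(pts)
    voxel_ml = h**3 / 1000.0
    counts = np.bincount(labels.ravel(), minlength=5)
    volumes_ml = {
        "blood": counts[LABEL_BLOOD] * voxel_ml,
        "myocardium": counts[LABEL_MYO] * voxel_ml,
        "scar": counts[LABEL_SCAR] * voxel_ml,
        "papillary": counts[LABEL_PAPILLARY] * voxel_ml,
    }
    myo_g = (volumes_ml["myocardium"] + volumes_ml["scar"]) * density
    scar_g = volumes_ml["scar"] * density
    truth = PhantomTruth(
        spec=spec,
        labels=labels,
        x=x,
        y=y,
        z=z,
        spacing=h,
        density=density,
        myo_mass=float(myo_g),
        scar_mass=float(scar_g),
        extent=float(100.0 * scar_g / myo_g),
        volumes_ml={k: float(v) for k, v in volumes_ml.items()},
    )
    return truth, phantom


def _rotation_matrix(angles_deg: tuple[float, float, float]) -> np.ndarray:
    ax, ay, az = np.radians(angles_deg)
    rx = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)], [0, np.sin(ax), np.cos(ax)]])
    ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0], [-np.sin(ay), 0, np.cos(ay)]])
    rz = np.array([[np.cos(az), -np.sin(az), 0], [np.sin(az), np.cos(az), 0], [0, 0, 1]])
    return rz @ ry @ rx


def _subsample_offsets(n: int, size: float) -> np.ndarray:
    """Midpoints of n equal sub-intervals of [-size/2, size/2]."""
    return (np.arange(n) + 0.5) / n * size - size / 2.0


def _rician(values: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return values
    n1 = rng.normal(0.0, sigma, values.shape)
    n2 = rng.normal(0.0, sigma, values.shape)
    return np.sqrt((values + n1) ** 2 + n2**2)


def _averaged_si(
    phantom: AnalyticPhantom,
    centers: np.ndarray,
    axes: np.ndarray,
    sizes: tuple[float, float, float],
) -> np.ndarray:
    """Partial-volume signal: mean analytic SI over each voxel footprint.

    ``centers`` has shape (..., 3); ``axes`` rows are the voxel edge
    directions and ``sizes`` the edge lengths (mm).  Sub-voxel pitch is
    ~0.25 mm per axis (at least 5 samples per axis).
    """
    ns = [max(5, int(round(s / _SUB_SPACING_MM))) for s in sizes]
    total = np.zeros(centers.shape[:-1])
    offs = [_subsample_offsets(n, s) for n, s in zip(ns, sizes)]
    for o0 in offs[0]:
        for o1 in offs[1]:
            for o2 in offs[2]:
                shift = o0 * axes[0] + o1 * axes[1] + o2 * axes[2]
                total += phantom.si(centers + shift)
    return total / (ns[0] * ns[1] * ns[2])


def acquire_isotropic(
    phantom: AnalyticPhantom,
    spacing: float = 1.25,
    oblique_deg: tuple[float, float, float] | None = (12.0, 8.0, 20.0),
    margin: float = 6.0,
    noise: bool = True,
) -> VolumeGrid:
    """Simulate the isotropic 3D acquisition of the phantom.

    The volume's index axes are rotated by ``oblique_deg`` relative to the
    phantom (LV) frame, so short-axis planes are genuinely oblique to the
    voxel lattice; ``oblique_deg=None`` keeps the lattice aligned with the
    LV axis (every k-slice is then a short-axis plane).  Voxel values are
    partial-volume averages of the analytic signal; Rician noise uses a
    stream derived from the spec seed.
    """
    spec = phantom.spec
    a, b, _ = spec.epi_semi_axes
    center = np.array([0.0, 0.0, spec.length / 2.0])
    half = np.array([a + margin, b + margin, spec.length / 2.0 + margin])
    axes = np.eye(3) if oblique_deg is None else _rotation_matrix(oblique_deg)
    ext = np.abs(axes) @ half  # half-extent along each rotated axis
    n = np.maximum(2, np.ceil(2 * ext / spacing).astype(int) + 1)
    spacing_v = np.full(3, float(spacing))
    origin = center - sum(
        (n[i] - 1) / 2.0 * spacing_v[i] * axes[i] for i in range(3)
    )
    ii = [np.arange(n[i], dtype=float) for i in range(3)]
    gi, gj, gk = np.meshgrid(*ii, indexing="ij")
    centers = (
        origin
        + gi[..., None] * spacing_v[0] * axes[0]
        + gj[..., None] * spacing_v[1] * axes[1]
        + gk[..., None] * spacing_v[2] * axes[2]
    )
    voxels = _averaged_si(phantom, centers, axes, (spacing, spacing, spacing))
    if noise and spec.noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 1]))
        voxels = _rician(voxels, spec.noise_sigma, rng)
    return VolumeGrid(voxels, origin, axes, spacing_v)


def sax_geometries(
    phantom: AnalyticPhantom,
    pixel_spacing: float = 1.4,
    thickness: float = 7.0,
    n_rows: int = 64,
    n_cols: int = 64,
    min_endo_radius: float = 3.0,
) -> list[SliceGeometry]:
    """Short-axis slice geometries covering the LV, base -> apex, no gap.

    Slices are perpendicular to the LV long axis (phantom z); slice centers
    start at ``thickness/2`` above the base and continue while the
    endocardial cross-section is at least ``min_endo_radius`` wide, so
    every slice can be contoured.
    """
    spec = phantom.spec
    geoms = []
    z = thickness / 2.0
    while True:
        endo = phantom.endo_axes_at(z)
        if endo is None or min(endo) < min_endo_radius:
            break
        origin = np.array(
            [
                -(n_cols - 1) / 2.0 * pixel_spacing,
                -(n_rows - 1) / 2.0 * pixel_spacing,
                z,
            ]
        )
        geoms.append(
            SliceGeometry(
                origin=origin,
                row_dir=np.array([1.0, 0.0, 0.0]),
                col_dir=np.array([0.0, 1.0, 0.0]),
                pixel_spacing=np.array([pixel_spacing, pixel_spacing]),
                n_rows=n_rows,
                n_cols=n_cols,
                thickness=thickness,
            )
        )
        z += thickness
    if len(geoms) < 3:
        raise InvalidParameterError(
            "phantom too short for a short-axis stack of >= 3 slices"
        )
    return geoms


def acquire_sax(
    phantom: AnalyticPhantom,
    geometries: list[SliceGeometry] | None = None,
    noise: bool = True,
) -> list[PlanarImage]:
    """Simulate the native 2D short-axis acquisition (1.4 mm, 7 mm slab).

    Each 2D voxel averages the analytic signal over its in-plane footprint
    and the full slab thickness (the 2D acquisition's through-plane partial
    volume), then Rician noise is added from a stream derived from the
    spec seed (independent of the 3D acquisition's stream).
    """
    spec = phantom.spec
    if geometries is None:
        geometries = sax_geometries(phantom)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 2]))
    images = []
    for geom in geometries:
        centers = geom.pixel_centers_world()
        axes = np.vstack([geom.row_dir, geom.col_dir, geom.normal])
        sizes = (float(geom.pixel_spacing[1]), float(geom.pixel_spacing[0]), geom.thickness)
        pixels = _averaged_si(phantom, centers, axes, sizes)
        if noise and spec.noise_sigma > 0:
            pixels = _rician(pixels, spec.noise_sigma, rng)
        images.append(
            PlanarImage(
                pixels,
                geom,
                np.ones(pixels.shape, dtype=bool),
                meta={"native": True, "slab_mm": geom.thickness},
            )
        )
    return images


# --------------------------------------------------------------------------
# Analytic contours: the phantom knows its own borders, so it can emit the
# endo/epi polygons and reference ROIs a human reader would otherwise draw.
# --------------------------------------------------------------------------

def _to_slice_frame(points: np.ndarray, geom: SliceGeometry) -> np.ndarray:
    d = np.asarray(points, dtype=float) - geom.origin
    return np.stack([d @ geom.row_dir, d @ geom.col_dir], axis=-1)


def _ellipse_polygon(
    geom: SliceGeometry, ax: float, ay: float, z: float, n_vertices: int = 180
):
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    world = np.stack(
        [ax * np.cos(theta), ay * np.sin(theta), np.full_like(theta, z)], axis=-1
    )
    from shapely.geometry import Polygon

    return Polygon(_to_slice_frame(world, geom))


def _disk_polygon(geom: SliceGeometry, cx: float, cy: float, z: float, radius: float):
    from shapely.geometry import Polygon

    theta = np.linspace(0.0, 2.0 * np.pi, 32, endpoint=False)
    world = np.stack(
        [cx + radius * np.cos(theta), cy + radius * np.sin(theta), np.full_like(theta, z)],
        axis=-1,
    )
    return Polygon(_to_slice_frame(world, geom))


def _ellipse_radius(ax: float, ay: float, phi_deg: float) -> float:
    phi = math.radians(phi_deg)
    return 1.0 / math.sqrt((math.cos(phi) / ax) ** 2 + (math.sin(phi) / ay) ** 2)


def _arc_roi(
    geom: SliceGeometry,
    endo_ax: tuple[float, float],
    epi_ax: tuple[float, float],
    z: float,
    phi_center_deg: float,
    span_deg: float = 60.0,
    half_width: float = 1.1,
):
    """Annular-sector ROI hugging the mid-wall (a reader's remote ROI)."""
    from shapely.geometry import Polygon

    phis = np.radians(phi_center_deg + np.linspace(-span_deg / 2, span_deg / 2, 24))
    pts = []
    for sign in (+1.0, -1.0):
        seq = phis if sign > 0 else phis[::-1]
        for phi in seq:
            pd = math.degrees(phi)
            r_endo = _ellipse_radius(*endo_ax, pd)
            r_epi = _ellipse_radius(*epi_ax, pd)
            hw = min(half_width, 0.25 * (r_epi - r_endo))
            r = 0.5 * (r_endo + r_epi) + sign * hw
            pts.append([r * math.cos(phi), r * math.sin(phi), z])
    return Polygon(_to_slice_frame(np.asarray(pts), geom))


def analytic_contours(
    phantom: AnalyticPhantom,
    geometries: list[SliceGeometry],
    roi_radius: float = 2.5,
    n_vertices: int = 180,
):
    """Ground-truth contour set for a short-axis stack.

    Every slice gets endo/epi borders, a remote ROI (mid-wall, opposite the
    scar sector), a blood-pool ROI and a normal-myocardium ROI; slices
    whose mid-plane intersects the scar's axial span also get a scar
    reference ROI centred inside the scar band.  Slices outside the span
    deliberately lack one, exercising the nearest-slice fallback exactly as
    enhancement-free slices do in patients.
    """
    from .quantify import ContourSet, SliceContours

    spec = phantom.spec
    sc = spec.scar
    entries = []
    for idx, geom in enumerate(geometries):
        z = float(geom.origin[2])
        endo_ax = phantom.endo_axes_at(z)
        epi_ax = phantom.epi_axes_at(z)
        if endo_ax is None or epi_ax is None:
            raise InvalidParameterError(
                f"slice {idx} at z={z:.1f} mm lies outside the contourable shell"
            )
        rois = {}

        def _mid_wall_disk(phi_deg: float, frac_from_endo: float, radius: float):
            r_endo = _ellipse_radius(*endo_ax, phi_deg)
            r_epi = _ellipse_radius(*epi_ax, phi_deg)
            r = r_endo + frac_from_endo * (r_epi - r_endo)
            radius = min(radius, 0.45 * (r_epi - r_endo))
            cx = r * math.cos(math.radians(phi_deg))
            cy = r * math.sin(math.radians(phi_deg))
            return _disk_polygon(geom, cx, cy, z, radius)

        remote_phi = (sc.center_angle_deg + 180.0) % 360.0
        rois["remote_roi"] = _arc_roi(geom, endo_ax, epi_ax, z, remote_phi)
        rois["myo_roi"] = _arc_roi(geom, endo_ax, epi_ax, z, remote_phi)
        rois["blood_roi"] = _disk_polygon(
            geom, 0.0, 0.0, z, min(8.0, 0.5 * min(endo_ax))
        )
        zf = z / spec.length
        if sc.z_span_frac[0] <= zf <= sc.z_span_frac[1]:
            # centre of the scar band through the wall
            if sc.kind == "ischemic":
                frac = 0.5 * sc.transmurality  # from endo outward
            else:  # centre of the outer-wall band, inside the spared rim
                frac = 1.0 - sc.epicardial_rim_frac - 0.5 * sc.transmurality
            wall = _ellipse_radius(*epi_ax, sc.center_angle_deg) - _ellipse_radius(
                *endo_ax, sc.center_angle_deg
            )
            band = sc.transmurality * wall
            rois["scar_roi"] = _mid_wall_disk(
                sc.center_angle_deg, frac, min(2.0, 0.4 * band)
            )
        entries.append(
            SliceContours(
                slice_index=idx,
                endo=_ellipse_polygon(geom, *endo_ax, z, n_vertices),
                epi=_ellipse_polygon(geom, *epi_ax, z, n_vertices),
                rois=rois,
            )
        )
    return ContourSet(entries)


def rv_insertion_points(
    phantom: AnalyticPhantom, geometries: list[SliceGeometry]
) -> np.ndarray:
    """World-coordinate anterior RV insertion point for every slice."""
    spec = phantom.spec
    pts = []
    for geom in geometries:
        z = float(geom.origin[2])
        epi_ax = phantom.epi_axes_at(z)
        r = _ellipse_radius(*epi_ax, spec.rv_insertion_angle_deg)
        phi = math.radians(spec.rv_insertion_angle_deg)
        pts.append([r * math.cos(phi), r * math.sin(phi), z])
    return np.asarray(pts)
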