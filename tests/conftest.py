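"""Shared fixtures: phantoms are expensive, so truths are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

from lgequant.geometry import SliceGeometry, VolumeGrid
from lgequant.phantom import (
    AnalyticPhantom,
    PhantomSpec,
    acquire_sax,
    analytic_contours,
    build_phantom,
    rv_insertion_points,
    sax_geometries,
)


def random_orthonormal_axes(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q.T


def make_volume(
    voxels: np.ndarray,
    origin=(0.0, 0.0, 0.0),
    axes=np.eye(3),
    spacing=(1.0, 1.0, 1.0),
) -> VolumeGrid:
    return VolumeGrid(np.asarray(voxels, float), np.asarray(origin), np.asarray(axes), np.asarray(spacing))


def make_slice(
    origin=(0.0, 0.0, 0.0),
    row_dir=(1.0, 0.0, 0.0),
    col_dir=(0.0, 1.0, 0.0),
    pixel_spacing=(1.0, 1.0),
    n_rows=8,
    n_cols=8,
    thickness=1.0,
) -> SliceGeometry:
    return SliceGeometry(
        origin=np.asarray(origin, float),
        row_dir=np.asarray(row_dir, float),
        col_dir=np.asarray(col_dir, float),
        pixel_spacing=np.asarray(pixel_spacing, float),
        n_rows=n_rows,
        n_cols=n_cols,
        thickness=thickness,
    )


@pytest.fixture(scope="session")
def ischemic_truth():
    """Fine-lattice truth + analytic phantom of the default infarct LV."""
    return build_phantom(PhantomSpec.ischemic(seed=1))


@pytest.fixture(scope="session")
def myocarditis_truth():
    return build_phantom(PhantomSpec.myocarditis(seed=1))


def acquire_native_bundle(spec: PhantomSpec, noise: bool = True) -> dict:
    """Native SAX acquisition with contours, without rebuilding truth."""
    ph = AnalyticPhantom(spec)
    geoms = sax_geometries(ph)
    return {
        "spec": spec,
        "phantom": ph,
        "geometries": geoms,
        "images": acquire_sax(ph, geoms, noise=noise),
        "contours": analytic_contours(ph, geoms),
        "insertion": rv_insertion_points(ph, geoms),
    }


@pytest.fixture(scope="session")
def ischemic_native(ischemic_truth):
    _, ph = ischemic_truth
    return acquire_native_bundle(ph.spec, noise=True)
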