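"""Shared fixtures: random generators, small meshes, and bundle builders."""

import numpy as np
import pytest

from swmlabel.geometry import K_POINTS
from swmlabel.labeling import BundleLabel, LabeledBundle, LabeledBundleSet
from swmlabel.synthetic import make_parcellated_mesh


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def sphere_mesh():
    """A 16-parcel icosphere mesh (642 vertices), radius 50 mm."""
    return make_parcellated_mesh(n_parcels=16, subdivisions=3, seed=0)


@pytest.fixture(scope="session")
def tiny_mesh():
    """A coarse 4-parcel icosphere for cheap intersection scans."""
    return make_parcellated_mesh(n_parcels=4, subdivisions=2, seed=1)


def straight_fiber(start, end, k=K_POINTS):
    """A straight resampled fiber from start to end."""
    return np.linspace(np.asarray(start, float), np.asarray(end, float), k)


def make_test_bundle(hemi, region_a, region_b, index, offset, n_fibers=12,
                     length=40.0):
    """A LabeledBundle whose centroid is a straight fiber at ``offset``."""
    offset = np.asarray(offset, float)
    centroid = straight_fiber(offset, offset + [length, 0, 0])
    fibers = np.stack([centroid] * n_fibers)
    return LabeledBundle(
        BundleLabel(hemi, region_a, region_b, index),
        np.arange(n_fibers), fibers, centroid, centroid[0].copy())


def make_subject_set(subject_id, bundle_specs):
    """LabeledBundleSet from (region_a, region_b, index, offset[, n]) tuples."""
    bundles = [make_test_bundle("lh", *spec) for spec in bundle_specs]
    return LabeledBundleSet(subject_id, bundles)


@pytest.fixture
def bundle_factory():
    return make_test_bundle


@pytest.fixture
def subject_factory():
    return make_subject_set
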