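"""Shared fixtures: all test data is generated in-process from the
synthetic phantom module; nothing is read from disk."""

from __future__ import annotations

import numpy as np
import pytest

import splinetrack as st
from splinetrack.synthetic_data import (
    BundleLayout,
    PhantomSpec,
    line_centerline,
    make_gradient_table,
    odf_field_from_directions,
    simulate_signal,
)


@pytest.fixture(scope="session")
def mesh():
    return st.SphereMesh.icosphere(3)


@pytest.fixture(scope="session")
def straight_phantom():
    """Single straight bundle along x in a small slab, with the full
    tensor + dODF reconstruction."""
    shape = (50, 11, 5)
    bundle = BundleLayout(line_centerline((2, 5, 2), (47, 5, 2)), radius=2.0)
    spec = PhantomSpec(
        shape=shape, voxel_size=(2.0, 2.0, 2.0), bundles=[bundle],
        gradient_table=make_gradient_table(64, 1500.0), noise_sigma=0.0,
    )
    dwi, truth, rois = simulate_signal(spec)
    tensors = st.fit_tensor(dwi)
    fa = st.fa_volume(tensors)
    odf = st.reconstruct_odf_field(dwi, mask=np.nan_to_num(fa.data) > 0.15)
    return {
        "dwi": dwi, "truth": truth, "rois": rois, "tensors": tensors,
        "fa": fa, "odf": odf, "bundle": bundle,
    }


@pytest.fixture(scope="session")
def crossing90():
    """Noiseless 90-degree two-tensor crossing phantom with tensor fit and
    dODF maxima over the crossing region."""
    dwi, truth, crossing = st.make_crossing_phantom(90.0)
    tensors = st.fit_tensor(dwi)
    fa = st.fa_volume(tensors)
    odf = st.reconstruct_odf_field(dwi, mask=np.nan_to_num(fa.data) > 0.1)
    return {
        "dwi": dwi, "truth": truth, "crossing": crossing,
        "tensors": tensors, "fa": fa, "odf": odf,
    }


@pytest.fixture(scope="session")
def fibercup():
    """Noiseless seven-bundle slab with reconstruction and the three
    tracker outputs (spline / euler-dODF / euler-tensor), seeded from the
    endpoint ROIs."""
    from splinetrack.streamline_tracker import DirectionProvider

    dwi, truth, roi_pairs = st.make_fibercup_like()
    tensors = st.fit_tensor(dwi)
    fa = st.fa_volume(tensors)
    famask = np.nan_to_num(fa.data) > 0.15
    odf = st.reconstruct_odf_field(dwi, mask=famask)
    params = st.TrackingParams(h=1.5, min_length=10.0)
    seed = np.zeros(dwi.spatial_shape, bool)
    for a, b in roi_pairs:
        seed |= a | b
    tracks = {
        "spline": st.track_wholefield(
            seed, fa, params, odf=odf, method="spline", voxel_size=dwi.voxel_size
        ),
        "euler-dodf": st.track_wholefield(
            seed, fa, params, provider=DirectionProvider.from_odf(odf),
            voxel_size=dwi.voxel_size,
        ),
        "euler-tensor": st.track_wholefield(
            seed, fa, params, provider=DirectionProvider.from_tensor(tensors),
            voxel_size=dwi.voxel_size,
        ),
    }
    return {
        "dwi": dwi, "truth": truth, "roi_pairs": roi_pairs, "fa": fa,
        "tensors": tensors, "odf": odf, "params": params, "tracks": tracks,
        "seed_mask": seed,
    }


@pytest.fixture()
def uniform_x_field():
    """Synthetic orientation field pointing along +x with constant FA."""
    shape = (60, 9, 5)
    dirs = np.zeros(shape + (3,))
    dirs[..., 0] = 1.0
    odf = odf_field_from_directions(dirs)
    fa = st.FAVolume(np.full(shape, 0.8), np.ones(shape, bool))
    return odf, fa
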