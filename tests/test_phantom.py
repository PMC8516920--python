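"""Synthetic paired NCCT/CECT phantom: construction invariants and I/O."""

import dataclasses

import numpy as np
import pytest

import scectgen.phantom as ph
from scectgen.phantom import (
    PhantomSpec,
    annotate_significant_nodes,
    generate_phantom_pair,
    read_phantom,
    vascular_mask,
    write_phantom,
)


def test_fixed_seed_is_bit_identical(small_spec):
    a = generate_phantom_pair(small_spec)
    b = generate_phantom_pair(small_spec)
    np.testing.assert_array_equal(a.ncct.hu, b.ncct.hu)
    np.testing.assert_array_equal(a.cect.hu, b.cect.hu)
    np.testing.assert_array_equal(a.masks, b.masks)


def test_noiseless_enhancement_is_exactly_the_delta(noiseless_pair):
    spec = noiseless_pair.spec
    diff = noiseless_pair.cect.hu - noiseless_pair.ncct.hu
    vasc = vascular_mask(noiseless_pair)
    nodes = noiseless_pair.masks >= ph.NODE_BASE
    np.testing.assert_array_equal(diff[vasc], spec.aorta_hu_post - spec.aorta_hu_pre)
    np.testing.assert_array_equal(diff[nodes], spec.node_hu_post - spec.node_hu_pre)
    np.testing.assert_array_equal(diff[~vasc & ~nodes], 0.0)


def test_uniform_node_enhancement_only_on_vascular_mask():
    spec = PhantomSpec(shape=(64, 64, 16), spacing=(4, 4, 8), noise_sd=0.0,
                       node_hu_pre=45.0, node_hu_post=45.0, seed=3)
    pair = generate_phantom_pair(spec)
    diff = pair.cect.hu - pair.ncct.hu
    vasc = vascular_mask(pair)
    np.testing.assert_array_equal(diff[vasc], 205.0)
    np.testing.assert_array_equal(diff[~vasc], 0.0)


def test_noiseless_region_means_match_spec(noiseless_pair):
    spec = noiseless_pair.spec
    m = noiseless_pair.masks
    hu = noiseless_pair.ncct.hu
    assert hu[m == ph.BODY].mean() == spec.body_hu
    assert hu[m == ph.LUNG].mean() == spec.lung_hu
    assert hu[m == ph.FAT].mean() == spec.fat_hu
    assert hu[m == ph.AORTA].mean() == spec.aorta_hu_pre
    assert hu[m == ph.AIR].mean() == -1000.0


def _mask_short_axis_mm(pair, ann):
    """Brute force: widest in-plane voxel row through the node at its slice."""
    sl = pair.masks[:, :, ann.slice_index] == ph.NODE_BASE + ann.lesion_id
    assert sl.any()
    sx, sy = pair.ncct.spacing[:2]
    x_extent = sl.any(axis=1).sum() * sx
    y_extent = sl.any(axis=0).sum() * sy
    return min(x_extent, y_extent)


def test_node_diameters_recoverable_from_masks():
    spec = PhantomSpec(seed=5)  # default 128x128x32 at 2.5 mm in-plane
    pair = generate_phantom_pair(spec)
    assert len(pair.annotations) == spec.n_nodes
    for ann in pair.annotations:
        measured = _mask_short_axis_mm(pair, ann)
        assert abs(measured - ann.short_axis_diameter_mm) <= pair.ncct.spacing[0]


def test_annotation_threshold_filtering(small_pair):
    pair = dataclasses.replace(small_pair)
    sizes = [4.0, 6.0, 12.0]
    pair = dataclasses.replace(
        small_pair,
        annotations=[
            dataclasses.replace(a, short_axis_diameter_mm=s)
            for a, s in zip(small_pair.annotations, sizes)
        ],
    )
    assert len(annotate_significant_nodes(pair, 5.0)) == 2
    # > 1 cm flags significant lymphadenopathy
    assert len(annotate_significant_nodes(pair, 10.0)) == 1
    assert annotate_significant_nodes(pair, 99.0) == []


def test_write_read_round_trip(tmp_path, small_pair):
    paths = write_phantom(small_pair, tmp_path / "pair0")
    back = read_phantom(tmp_path / "pair0")
    np.testing.assert_array_equal(back.ncct.hu, small_pair.ncct.hu)
    np.testing.assert_array_equal(back.cect.hu, small_pair.cect.hu)
    np.testing.assert_array_equal(back.masks, small_pair.masks)
    assert back.ncct.spacing == small_pair.ncct.spacing
    import pandas as pd

    assert len(pd.read_csv(paths["annotations"])) == len(small_pair.annotations)


def test_spacing_survives_round_trip(tmp_path):
    spec = PhantomSpec(shape=(32, 32, 16), spacing=(1.0, 1.0, 3.0), n_nodes=0,
                       n_vessels=0, seed=2)
    pair = generate_phantom_pair(spec)
    write_phantom(pair, tmp_path / "p")
    assert read_phantom(tmp_path / "p").ncct.spacing == (1.0, 1.0, 3.0)


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        PhantomSpec(aorta_hu_pre=100.0, aorta_hu_post=50.0)
    with pytest.raises(ValueError):
        PhantomSpec(noise_sd=-1.0)
    with pytest.raises(ValueError):
        PhantomSpec(node_diameter_range=(0.0, 10.0))
    with pytest.raises(ValueError):
        PhantomSpec(shape=(4, 4, 4))


def test_too_small_volume_fails_descriptively():
    spec = PhantomSpec(shape=(16, 16, 8), spacing=(2.0, 2.0, 4.0),
                       node_diameter_range=(28.0, 30.0), seed=0)
    with pytest.raises(ValueError, match="too small"):
        generate_phantom_pair(spec)
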