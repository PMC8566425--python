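"""Synthetic scene generator: geometry, placement, rendering, ground truth."""

import numpy as np
import pytest

from mammilieu.masks import FSR, ILS, PE
from mammilieu.simulate.scene import (
    OvercrowdedSceneError,
    SceneSpec,
    generate_scene,
)
from mammilieu.stains import deconvolve, marker_pass_matrix, rgb_to_od


def test_zero_density_scene_has_no_cells():
    spec = SceneSpec(image_size_px=(256, 256), seed=1)
    rgb, truth = generate_scene(spec)
    assert truth.cells == []
    assert rgb.shape == (256, 256, 3)


def test_pe_fraction_zero_puts_all_cells_in_ils():
    spec = SceneSpec(
        image_size_px=(384, 384),
        pe_fraction_of_eer=0.0,
        planted_density={("T", "ILS"): 200.0},
        seed=2,
    )
    _, truth = generate_scene(spec)
    assert len(truth.cells) > 0
    assert all(c.true_compartment == "ILS" for c in truth.cells)
    assert truth.compartment_mask.pixel_count(PE) == 0


def test_masks_partition_image_and_areas_are_consistent():
    spec = SceneSpec(image_size_px=(300, 300), eer_fraction=0.5, seed=3)
    _, truth = generate_scene(spec)
    mask = truth.compartment_mask
    counts = {lab: mask.pixel_count(lab) for lab in (FSR, PE, ILS)}
    assert sum(counts.values()) == 300 * 300
    assert mask.area_mm2(PE) == counts[PE] * (0.465e-3) ** 2
    # EER fraction matched by the quantile threshold to within a pixel row
    assert abs((counts[PE] + counts[ILS]) / (300 * 300) - 0.5) < 0.02


def test_cell_centroids_lie_in_their_compartment_and_counts_balance():
    spec = SceneSpec(
        image_size_px=(512, 512),
        planted_density={("T", "PE"): 300.0, ("B", "ILS"): 200.0},
        seed=4,
    )
    _, truth = generate_scene(spec)
    name = {PE: "PE", ILS: "ILS"}
    for c in truth.cells:
        y, x = c.centroid_px
        assert name[truth.compartment_mask.label_at(y, x)] == c.true_compartment
    # realized density is exactly count / area for every planted key
    counts = truth.counts()
    for key, dens in truth.planted_density_realized.items():
        area = truth.compartment_mask.area_mm2(PE if key[1] == "PE" else ILS)
        assert dens == pytest.approx(counts.get(key, 0) / area)


def test_generation_is_bit_deterministic():
    spec = SceneSpec(
        image_size_px=(256, 256),
        planted_density={("Mac", "ILS"): 150.0},
        cd68_speckle_fraction=0.2,
        seed=7,
    )
    rgb1, t1 = generate_scene(spec)
    rgb2, t2 = generate_scene(spec)
    assert np.array_equal(rgb1, rgb2)
    assert [c.centroid_px for c in t1.cells] == [c.centroid_px for c in t2.cells]
    assert np.array_equal(t1.compartment_mask.labels, t2.compartment_mask.labels)


def test_planted_count_matches_poisson_expectation():
    # ILS T cells at 259 cells/mm^2: count ~ Poisson(density * area)
    spec = SceneSpec(
        image_size_px=(1024, 1024),
        eer_fraction=0.9,
        pe_fraction_of_eer=0.1,
        planted_density={("T", "ILS"): 259.0},
        seed=8,
    )
    _, truth = generate_scene(spec)
    area = truth.compartment_mask.area_mm2(ILS)
    lam = 259.0 * area
    n = len(truth.cells)
    assert abs(n - lam) < 4 * np.sqrt(lam)


def test_rendered_cell_recovers_planted_concentration(registry):
    spec = SceneSpec(
        image_size_px=(256, 256),
        eer_fraction=1.0,
        pe_fraction_of_eer=0.0,
        planted_density={("Mac", "ILS"): 80.0},
        background_od_noise=0.0,
        seed=9,
    )
    rgb, truth = generate_scene(spec)
    assert truth.cells, "expected at least one planted cell"
    stack = deconvolve(rgb_to_od(rgb), marker_pass_matrix("yellow", registry))
    yellow = stack.channel("yellow")
    cell = truth.cells[0]
    y, x = cell.centroid_px
    # at the halo interior the planted amplitude comes back (quantization only)
    assert yellow[y, x] == pytest.approx(cell.amplitude, abs=0.05)
    # far from any cell the yellow channel is clean
    far = yellow.copy()
    for c in truth.cells:
        cy, cx = c.centroid_px
        r = int(c.diameter_um / 0.465) + 2
        far[max(0, cy - r) : cy + r, max(0, cx - r) : cx + r] = 0
    assert np.abs(far).max() < 0.05


def test_overcrowded_scene_raises():
    spec = SceneSpec(
        image_size_px=(128, 128),
        eer_fraction=0.3,
        pe_fraction_of_eer=0.0,
        planted_density={("T", "ILS"): 50000.0},
        seed=10,
    )
    with pytest.raises(OvercrowdedSceneError):
        generate_scene(spec)


def test_image_too_small_for_requested_eer():
    spec = SceneSpec(image_size_px=(4, 4), eer_fraction=0.01, seed=1)
    with pytest.raises(ValueError, match="too small"):
        generate_scene(spec)


def test_spec_validation_rejects_bad_values():
    with pytest.raises(ValueError):
        SceneSpec(eer_fraction=1.2).validate()
    with pytest.raises(ValueError):
        SceneSpec(planted_density={("T", "PE"): -5.0}).validate()
    with pytest.raises(ValueError):
        SceneSpec(panel="double", planted_density={("T", "PE"): 5.0}).validate()


def test_double_panel_m2_double_positive_renders_both_chromogens():
    spec = SceneSpec(
        image_size_px=(512, 512),
        panel="double",
        planted_density={("M2", "ILS"): 150.0},
        m2_double_positive_fraction=1.0,
        seed=12,
    )
    _, truth = generate_scene(spec)
    assert truth.cells
    assert all(set(c.chromogens) == {"teal", "yellow"} for c in truth.cells)


def test_speckles_have_no_nucleus_and_debris_is_small():
    spec = SceneSpec(
        image_size_px=(768, 768),
        eer_fraction=0.9,
        planted_density={("Mac", "ILS"): 150.0},
        cd68_speckle_fraction=0.3,
        debris_per_mm2=60.0,
        seed=13,
    )
    _, truth = generate_scene(spec)
    assert truth.speckles and truth.debris
    assert all(not s.has_nucleus for s in truth.speckles)
    assert all(d.diameter_um < 15.0 for d in truth.debris)
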