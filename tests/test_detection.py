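"""Cell detection: filters, nucleus rule, classification, compartments."""

import numpy as np
import pytest

from mammilieu.detection import (
    DetectionParams,
    assign_compartment,
    associate_nucleus,
    classify_cells,
    detect_candidates,
    detect_scene,
    retained,
)
from mammilieu.masks import FSR, ILS, PE, CompartmentMask
from mammilieu.segmentation import oracle_segmenter

PX = 0.465


def _disk_map(diameter_um, value, size=256, center=None):
    """White (255) background with one disk of the given intensity."""
    img = np.full((size, size), 255.0)
    cy, cx = center or (size // 2, size // 2)
    r = diameter_um / 2 / PX
    yy, xx = np.ogrid[:size, :size]
    img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = value
    return img


def test_retention_rule_is_sharp_at_both_boundaries():
    p = DetectionParams()
    # "< 15 um filtered out" is exclusive: 15.0 survives
    assert retained(15.0, 30.0, p)
    assert not retained(14.999, 30.0, p)
    # "intensity < 50 positive" is exclusive: 50.0 is not positive
    assert retained(20.0, 49.999, p)
    assert not retained(20.0, 50.0, p)


def test_single_dark_disk_yields_one_object():
    objs, _ = detect_candidates(_disk_map(20.0, 30.0), DetectionParams())
    assert len(objs) == 1
    assert objs[0].equivalent_diameter_um == pytest.approx(20.0, rel=0.15)
    assert objs[0].mean_intensity < 50


def test_small_disk_removed_by_size_filter():
    objs, _ = detect_candidates(_disk_map(10.0, 30.0), DetectionParams())
    assert objs == []


def test_dim_disk_removed_by_positivity_filter():
    objs, _ = detect_candidates(_disk_map(20.0, 60.0), DetectionParams())
    assert objs == []


def test_touching_disks_are_split_by_watershed():
    img = np.full((256, 256), 255.0)
    for cx in (100, 100 + int(21 / PX)):  # tangent 21-um disks
        yy, xx = np.ogrid[:256, :256]
        img[(yy - 128) ** 2 + (xx - cx) ** 2 <= (10.5 / PX) ** 2] = 25.0
    objs, _ = detect_candidates(img, DetectionParams())
    assert len(objs) == 2


def test_detection_translation_invariance():
    img1 = _disk_map(20.0, 30.0, center=(100, 100))
    img2 = np.roll(np.roll(img1, 13, axis=0), 7, axis=1)
    o1, _ = detect_candidates(img1, DetectionParams())
    o2, _ = detect_candidates(img2, DetectionParams())
    assert len(o1) == len(o2) == 1
    assert o2[0].centroid_px[0] - o1[0].centroid_px[0] == pytest.approx(13, abs=0.5)
    assert o1[0].area_px == o2[0].area_px


def test_nucleus_association_keeps_nucleated_drops_speckles():
    p = DetectionParams()
    cd68 = _disk_map(20.0, 30.0, center=(60, 60))
    cd68[_disk_map(20.0, 30.0, center=(180, 180)) < 255] = 30.0  # second, nucleus-free
    objs, labels = detect_candidates(cd68, p)
    assert len(objs) == 2
    nucleus = _disk_map(8.0, 20.0, center=(60, 60))
    _, nlabels = detect_candidates(nucleus, p.nucleus_variant())
    kept, _ = associate_nucleus(objs, labels, nlabels, p)
    assert len(kept) == 1
    assert kept[0].centroid_px[0] == pytest.approx(60, abs=1)


def _objects_for(*centers, value=30.0):
    img = np.full((256, 256), 255.0)
    for cy, cx in centers:
        yy, xx = np.ogrid[:256, :256]
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= (10 / PX) ** 2] = value
    return detect_candidates(img, DetectionParams())


def test_triple_panel_classification_rules():
    empty = ([], np.zeros((256, 256), dtype=np.int32))
    cd3 = _objects_for((60, 60))
    cells = classify_cells({"CD3": cd3, "CD20": empty, "CD68": empty}, "triple")
    assert [c.cell_class for c in cells] == ["T"]

    cd20 = _objects_for((60, 60))
    cells = classify_cells({"CD3": empty, "CD20": cd20, "CD68": empty}, "triple")
    assert [c.cell_class for c in cells] == ["B"]

    # spatial collision CD3+CD20 at the same location -> unclassified
    cells = classify_cells({"CD3": cd3, "CD20": cd20, "CD68": empty}, "triple")
    assert [c.cell_class for c in cells] == ["unclassified"]


def test_double_panel_cd163_dominates():
    empty = ([], np.zeros((256, 256), dtype=np.int32))
    cd68 = _objects_for((60, 60))
    cd163 = _objects_for((60, 60))
    cells = classify_cells({"CD68": cd68, "CD163": cd163}, "double")
    assert [c.cell_class for c in cells] == ["M2"]  # double positive is M2
    cells = classify_cells({"CD68": cd68, "CD163": empty}, "double")
    assert [c.cell_class for c in cells] == ["M1"]
    cells = classify_cells({"CD68": empty, "CD163": cd163}, "double")
    assert [c.cell_class for c in cells] == ["M2"]


def test_distant_objects_do_not_merge():
    empty = ([], np.zeros((256, 256), dtype=np.int32))
    cd3 = _objects_for((60, 60))
    cd20 = _objects_for((180, 180))
    cells = classify_cells({"CD3": cd3, "CD20": cd20, "CD68": empty}, "triple")
    assert sorted(c.cell_class for c in cells) == ["B", "T"]


def _toy_mask():
    labels = np.zeros((100, 100), dtype=np.uint8)
    labels[:, 40:70] = ILS
    labels[:, 70:] = PE
    return CompartmentMask(labels=labels, pixel_size_um=PX)


def test_assign_compartment_from_centroid():
    from mammilieu.detection import DetectedCell

    cells = [
        DetectedCell(0, (50.0, 80.0), 20.0, {}),
        DetectedCell(1, (50.0, 50.0), 20.0, {}),
        DetectedCell(2, (50.0, 10.0), 20.0, {}),
    ]
    out = assign_compartment(cells, _toy_mask())
    assert [c.compartment for c in out] == ["PE", "ILS", "outside"]


def test_assign_compartment_rejects_out_of_frame_centroid():
    from mammilieu.detection import DetectedCell

    with pytest.raises(ValueError, match="outside image"):
        assign_compartment([DetectedCell(0, (500.0, 500.0), 20.0, {})], _toy_mask())


def test_end_to_end_recall_precision_per_class(mixed_scene):
    """Oracle segmentation + detection recovers the planted cells at >= 95%
    recall and precision per class, with speckles and debris excluded."""
    spec, rgb, truth = mixed_scene
    cells = detect_scene(rgb, DetectionParams(), panel="triple")
    cells = assign_compartment(cells, oracle_segmenter(truth))

    planted = {}
    for c in truth.cells:
        planted.setdefault(c.true_class, []).append(c.centroid_px)
    detected = {}
    for c in cells:
        if c.cell_class in ("T", "B", "Mac"):
            detected.setdefault(c.cell_class, []).append(c.centroid_px)

    tol_px = 10.0 / PX
    for cls, truth_pts in planted.items():
        det = np.array(detected.get(cls, []))
        hits = 0
        for ty, tx in truth_pts:
            if len(det) and np.min(np.hypot(det[:, 0] - ty, det[:, 1] - tx)) < tol_px:
                hits += 1
        recall = hits / len(truth_pts)
        precision = min(1.0, hits / max(len(det), 1))
        assert recall >= 0.95, f"{cls} recall {recall:.3f}"
        assert precision >= 0.95, f"{cls} precision {precision:.3f}"

    # class counts inside EER partition exactly into PE + ILS
    for cls in ("T", "B", "Mac"):
        n_pe = sum(1 for c in cells if c.cell_class == cls and c.compartment == "PE")
        n_ils = sum(1 for c in cells if c.cell_class == cls and c.compartment == "ILS")
        n_eer = sum(
            1 for c in cells if c.cell_class == cls and c.compartment in ("PE", "ILS")
        )
        assert n_pe + n_ils == n_eer


def test_speckle_exclusion_matches_nucleated_truth(mixed_scene):
    """With 20% planted nucleus-free speckles, retained CD68 count equals
    the nucleated planted count within 5%."""
    spec, rgb, truth = mixed_scene
    cells = detect_scene(rgb, DetectionParams(), panel="triple", markers=["CD68"])
    n_mac_detected = sum(1 for c in cells if c.cell_class == "Mac")
    n_mac_planted = sum(1 for c in truth.cells if c.true_class == "Mac")
    assert truth.speckles, "fixture should contain speckles"
    assert n_mac_detected == pytest.approx(n_mac_planted, rel=0.05)


def test_double_panel_end_to_end_m1_m2():
    """Full detection on a double-stained scene separates CD68+/CD163-
    (M1) from CD163+ (M2, half double-positive) populations."""
    from mammilieu.simulate.scene import SceneSpec, generate_scene

    spec = SceneSpec(
        image_size_px=(768, 768),
        panel="double",
        eer_fraction=0.9,
        pe_fraction_of_eer=0.2,
        planted_density={("M1", "ILS"): 80.0, ("M2", "ILS"): 120.0},
        m2_double_positive_fraction=0.5,
        seed=21,
    )
    rgb, truth = generate_scene(spec)
    cells = detect_scene(rgb, DetectionParams(), panel="double")
    n = {"M1": 0, "M2": 0}
    for c in cells:
        if c.cell_class in n:
            n[c.cell_class] += 1
    planted = truth.counts()
    assert n["M1"] == pytest.approx(planted[("M1", "ILS")], rel=0.1)
    assert n["M2"] == pytest.approx(planted[("M2", "ILS")], rel=0.1)


def test_missing_pixel_size_rejected():
    with pytest.raises(ValueError):
        DetectionParams(pixel_size_um=0.0)
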