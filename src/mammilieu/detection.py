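"""Detection, filtering and classification of chromogen-stained cells.

Per marker, the deconvolved concentration channel is mapped to the 0-255
intensity convention (0 = strongest stain), smoothed with a mean filter,
binarized, and split into individual blobs by a watershed at the
characteristic blob scale (33 um).  Binary objects with equivalent-circle
diameter below 15 um are discarded, and objects whose mean intensity is not
below 50 are discarded as non-positive.  CD68 objects must additionally
overlap a hematoxylin nucleus object ("speckles" without an associated
nucleus are excluded).  Surviving objects are merged across markers by
spatial overlap into cells and classified:

triple panel: CD3+/CD20-/CD68- -> T, CD3-/CD20+/CD68- -> B,
    CD3-/CD20-/CD68+ -> Mac; any multi-positive cell -> unclassified.
double panel: CD163+ -> M2 (regardless of CD68), CD68+/CD163- -> M1.

Boundary conventions: "< 15 um" is exclusive (a 15.0 um object is kept);
"intensity < 50" is exclusive (a mean of exactly 50.0 is not positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import watershed

from mammilieu.masks import FSR, PE, ILS, CompartmentMask
from mammilieu.stains import (
    channel_to_intensity,
    deconvolve,
    load_stain_registry,
    marker_pass_matrix,
    rgb_to_od,
)

__all__ = [
    "DetectionParams",
    "BinaryObject",
    "DetectedCell",
    "retained",
    "detect_candidates",
    "associate_nucleus",
    "classify_cells",
    "assign_compartment",
    "detect_scene",
    "PANEL_MARKERS",
]

#: Marker -> chromogen per panel (must agree with the stain registry).
PANEL_MARKERS = {
    "triple": {"CD3": "purple", "CD20": "teal", "CD68": "yellow"},
    "double": {"CD68": "yellow", "CD163": "teal"},
}


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds of the detection stage; lengths in um so they are
    independent of scan resolution."""

    pixel_size_um: float = 0.465
    mean_filter_radius_um: float = 2.0
    blob_scale_um: float = 33.0
    min_object_um: float = 15.0
    positivity_intensity_threshold: float = 50.0
    binarize_intensity: float = 128.0
    intensity_scale: float = 1.0
    nucleus_overlap_min: float = 0.01
    merge_overlap_min: float = 0.30
    # the hematoxylin-nucleus pass reuses the machinery with its own cutoffs
    nucleus_min_um: float = 4.0
    nucleus_binarize_intensity: float = 40.0
    nucleus_mean_filter_radius_um: float = 1.0

    def __post_init__(self) -> None:
        for name in ("pixel_size_um", "mean_filter_radius_um", "blob_scale_um", "min_object_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.positivity_intensity_threshold < 255):
            raise ValueError("positivity_intensity_threshold must be in (0, 255)")

    def nucleus_variant(self) -> "DetectionParams":
        return replace(
            self,
            min_object_um=self.nucleus_min_um,
            binarize_intensity=self.nucleus_binarize_intensity,
            mean_filter_radius_um=self.nucleus_mean_filter_radius_um,
        )


@dataclass
class BinaryObject:
    """One binary object from a single marker channel."""

    label: int
    centroid_px: tuple[float, float]
    area_px: int
    equivalent_diameter_um: float
    mean_intensity: float


@dataclass
class DetectedCell:
    id: int
    centroid_px: tuple[float, float]
    equivalent_diameter_um: float
    positivity: dict[str, bool]
    mean_intensity: dict[str, float] = field(default_factory=dict)
    cell_class: str = "unclassified"
    compartment: str = "outside"  # "PE" | "ILS" | "outside"


def retained(equivalent_diameter_um: float, mean_intensity: float, params: DetectionParams) -> bool:
    """Retention rule for a binary object: at least 15 um equivalent
    diameter (objects *less than* 15 um are filtered out) and mean
    intensity strictly below 50 (positive)."""
    return (
        equivalent_diameter_um >= params.min_object_um
        and mean_intensity < params.positivity_intensity_threshold
    )


def detect_candidates(
    intensity_map: np.ndarray, params: DetectionParams
) -> tuple[list[BinaryObject], np.ndarray]:
    """Segment one 0-255 intensity channel into retained binary objects.

    Returns (objects, label_image); the label image keeps only retained
    objects (others zeroed) so downstream overlap logic sees survivors only.
    """
    if params.pixel_size_um is None or params.pixel_size_um <= 0:
        raise ValueError("pixel size missing: um thresholds cannot be applied")
    img = np.asarray(intensity_map, dtype=float)
    size = max(1, int(round(2 * params.mean_filter_radius_um / params.pixel_size_um)) | 1)
    smoothed = ndi.uniform_filter(img, size=size, mode="nearest")
    binary = smoothed < params.binarize_intensity
    labels = np.zeros(img.shape, dtype=np.int32)
    if not binary.any():
        return [], labels
    cc, _ = ndi.label(binary)
    dist = ndi.distance_transform_edt(binary)
    min_dist = max(3, int(round(0.4 * params.blob_scale_um / params.pixel_size_um)))
    peaks = peak_local_max(dist, min_distance=min_dist, labels=cc, exclude_border=False)
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dist, markers, mask=binary)

    objects: list[BinaryObject] = []
    keep = np.zeros(labels.max() + 1, dtype=bool)
    for rp in regionprops(labels, intensity_image=smoothed):
        eq_um = 2.0 * np.sqrt(rp.area / np.pi) * params.pixel_size_um
        if retained(eq_um, float(rp.intensity_mean), params):
            keep[rp.label] = True
            objects.append(
                BinaryObject(
                    label=rp.label,
                    centroid_px=tuple(rp.centroid),
                    area_px=int(rp.area),
                    equivalent_diameter_um=eq_um,
                    mean_intensity=float(rp.intensity_mean),
                )
            )
    labels = np.where(keep[labels], labels, 0)
    return objects, labels


def associate_nucleus(
    cd68_objects: list[BinaryObject],
    cd68_labels: np.ndarray,
    nucleus_labels: np.ndarray,
    params: DetectionParams,
) -> tuple[list[BinaryObject], np.ndarray]:
    """Drop CD68 objects whose overlap with hematoxylin nucleus objects is
    below nucleus_overlap_min of the object area (nucleus-free speckles)."""
    if not cd68_objects:
        return [], cd68_labels
    nuc = nucleus_labels > 0
    idx = [o.label for o in cd68_objects]
    inter = ndi.sum_labels(nuc.astype(float), labels=cd68_labels, index=idx)
    kept, keep_labels = [], set()
    for obj, ov in zip(cd68_objects, inter):
        if ov / obj.area_px >= max(params.nucleus_overlap_min, 1e-12):
            kept.append(obj)
            keep_labels.add(obj.label)
    out = np.where(np.isin(cd68_labels, list(keep_labels)), cd68_labels, 0)
    return kept, out


def _overlaps(la: np.ndarray, lb: np.ndarray) -> dict[tuple[int, int], int]:
    both = (la > 0) & (lb > 0)
    if not both.any():
        return {}
    pairs = np.stack([la[both], lb[both]])
    uniq, counts = np.unique(pairs, axis=1, return_counts=True)
    return {(int(a), int(b)): int(c) for (a, b), c in zip(uniq.T, counts)}


def classify_cells(
    marker_objects: dict[str, tuple[list[BinaryObject], np.ndarray]],
    panel: str,
) -> list[DetectedCell]:
    """Merge per-marker objects into cells by spatial overlap and apply the
    panel's classification rules.

    Objects from different markers overlapping by at least
    merge_overlap_min of the smaller object are one cell (co-localization
    in the double panel, a collision in the triple panel).
    """
    if panel not in PANEL_MARKERS:
        raise ValueError(f"unknown panel {panel!r}")
    markers = [m for m in PANEL_MARKERS[panel] if m in marker_objects]

    nodes = [(m, o) for m in markers for o in marker_objects[m][0]]
    parent = {i: i for i in range(len(nodes))}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    index = {(m, o.label): i for i, (m, o) in enumerate(nodes)}
    area = {(m, o.label): o.area_px for m, o in nodes}
    for ma, mb in combinations(markers, 2):
        ov = _overlaps(marker_objects[ma][1], marker_objects[mb][1])
        for (la, lb), inter in ov.items():
            if inter >= 0.30 * min(area[(ma, la)], area[(mb, lb)]):
                union(index[(ma, la)], index[(mb, lb)])

    groups: dict[int, list[int]] = {}
    for i in range(len(nodes)):
        groups.setdefault(find(i), []).append(i)

    cells: list[DetectedCell] = []
    for cid, members in enumerate(sorted(groups.values(), key=min)):
        objs = [nodes[i] for i in members]
        tot = sum(o.area_px for _, o in objs)
        cy = sum(o.centroid_px[0] * o.area_px for _, o in objs) / tot
        cx = sum(o.centroid_px[1] * o.area_px for _, o in objs) / tot
        flags = {m: False for m in PANEL_MARKERS[panel]}
        intens: dict[str, float] = {}
        for m, o in objs:
            flags[m] = True
            intens[m] = min(intens.get(m, 255.0), o.mean_intensity)
        cells.append(
            DetectedCell(
                id=cid,
                centroid_px=(cy, cx),
                equivalent_diameter_um=max(o.equivalent_diameter_um for _, o in objs),
                positivity=flags,
                mean_intensity=intens,
                cell_class=_classify(flags, panel),
            )
        )
    return cells


def _classify(flags: dict[str, bool], panel: str) -> str:
    if panel == "triple":
        pos = {m for m, v in flags.items() if v}
        if pos == {"CD3"}:
            return "T"
        if pos == {"CD20"}:
            return "B"
        if pos == {"CD68"}:
            return "Mac"
        return "unclassified"
    # double panel: CD163+ is M2 whether or not CD68 co-stains
    if flags.get("CD163"):
        return "M2"
    if flags.get("CD68"):
        return "M1"
    return "unclassified"


def assign_compartment(cells: list[DetectedCell], mask: CompartmentMask) -> list[DetectedCell]:
    """Set each cell's compartment from the mask label at its centroid;
    centroids in FSR are "outside" and excluded from EER densities."""
    rows, cols = mask.shape
    names = {PE: "PE", ILS: "ILS", FSR: "outside"}
    for cell in cells:
        r, c = int(round(cell.centroid_px[0])), int(round(cell.centroid_px[1]))
        if not (0 <= r < rows and 0 <= c < cols):
            raise ValueError(f"cell {cell.id} centroid outside image")
        cell.compartment = names[mask.label_at(r, c)]
    return cells


def detect_scene(
    rgb: np.ndarray,
    params: DetectionParams,
    panel: str = "triple",
    markers: list[str] | None = None,
    registry=None,
) -> list[DetectedCell]:
    """Full detection on one RGB scene: per-marker deconvolution passes,
    candidate segmentation, CD68 nucleus association, and classification.

    ``markers`` may restrict the passes (e.g. a slide stained for one
    marker); the classification rules still see the full panel with the
    omitted markers negative.
    """
    reg = registry if registry is not None else load_stain_registry()
    chromogen = PANEL_MARKERS[panel]
    run = markers if markers is not None else list(chromogen)
    od = rgb_to_od(rgb)

    # hematoxylin pass (for the CD68 nucleus rule), unmixed against yellow
    h_mat = marker_pass_matrix("yellow", reg)
    h_stack = deconvolve(od, h_mat)
    h_int = channel_to_intensity(h_stack.channel("hematoxylin"), params.intensity_scale)
    _, nucleus_labels = detect_candidates(h_int, params.nucleus_variant())

    marker_objects: dict[str, tuple[list[BinaryObject], np.ndarray]] = {}
    for m in run:
        stack = deconvolve(od, marker_pass_matrix(chromogen[m], reg))
        inten = channel_to_intensity(stack.channel(chromogen[m]), params.intensity_scale)
        objs, labels = detect_candidates(inten, params)
        if m == "CD68":
            objs, labels = associate_nucleus(objs, labels, nucleus_labels, params)
        marker_objects[m] = (objs, labels)
    return classify_cells(marker_objects, panel)
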