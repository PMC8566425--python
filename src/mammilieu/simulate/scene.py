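"""Synthetic multiplex brightfield IHC scene generator.

A scene emulates a scanned FFPE breast-tissue section at 0.465 um/pixel:
smooth epithelium-enriched regions (EER) on a fat/stroma background (FSR),
duct/alveolar foci inside EER defining the peri-epithelium (PE), the rest of
EER being intralobular stroma (ILS).  Immune cells are planted as a
hematoxylin nucleus disk plus a chromogen halo and the image is rendered by
Beer-Lambert composition of per-stain optical densities, so that color
deconvolution with the same stain matrix recovers the planted
concentrations.

Panels
------
triple : CD3 (purple) / CD20 (teal) / CD68 (yellow) + hematoxylin; classes
    "T", "B", "Mac".
double : CD68 (yellow) / CD163 (teal) + hematoxylin; classes "M1"
    (CD68+/CD163-) and "M2" (CD163+, a configurable fraction of which is
    double-positive and renders as the yellow+teal mixture, i.e. green).

Ground truth records every planted object (cells, nucleus-free CD68
"speckles", sub-15-um debris) together with the compartment label map and
realized per-class densities, so detection and quantification can be scored
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, zoom

from mammilieu.masks import FSR, PE, ILS, LABEL_NAMES, CompartmentMask
from mammilieu.stains import load_stain_registry, od_to_rgb

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "PlantedObject",
    "generate_scene",
    "OvercrowdedSceneError",
    "PANEL_CLASSES",
    "CLASS_CHROMOGEN",
]

#: Immune cell classes per panel.
PANEL_CLASSES = {"triple": ("T", "B", "Mac"), "double": ("M1", "M2")}

#: Chromogen(s) rendered for each class (M2 may add yellow, see below).
CLASS_CHROMOGEN = {"T": "purple", "B": "teal", "Mac": "yellow", "M1": "yellow", "M2": "teal"}

#: Background hematoxylin concentration by compartment label.  PE is the
#: epithelial band (nucleus-dense, strong counterstain), ILS light stroma,
#: FSR nearly blank (fat).
BACKGROUND_HEMATOXYLIN = {FSR: 0.05, ILS: 0.18, PE: 0.55}


class OvercrowdedSceneError(RuntimeError):
    """Raised when the requested density cannot be placed under the
    hard-core separation constraint."""


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene.

    planted_density maps (cell_class, compartment_name) -> cells/mm^2 with
    compartment_name in {"PE", "ILS"}.  cell_diameter_um is the nucleus
    equivalent diameter (biological cell body); the chromogen halo that
    detection sees is drawn from halo_diameter_um and floored at
    halo_min_um, above the 15 um detection cutoff, so planted cells survive
    the size filter while debris (debris_per_mm2, diameter < 15 um)
    exercises it.
    """

    image_size_px: tuple[int, int] = (1024, 1024)
    pixel_size_um: float = 0.465
    eer_fraction: float = 0.6
    pe_fraction_of_eer: float = 0.3
    panel: str = "triple"
    planted_density: dict[tuple[str, str], float] = field(default_factory=dict)
    cell_diameter_um: tuple[float, float] = (8.0, 1.5)
    halo_diameter_um: tuple[float, float] = (20.0, 1.5)
    halo_min_um: float = 16.0
    chromogen_amplitude: tuple[float, float] = (1.3, 0.08)
    nucleus_amplitude: float = 1.2
    cd68_speckle_fraction: float = 0.0
    debris_per_mm2: float = 0.0
    nucleus_diameter_clip_um: tuple[float, float] = (6.0, 12.0)
    debris_diameter_um: tuple[float, float] = (8.0, 1.5)
    m2_double_positive_fraction: float = 0.5
    min_separation_um: float | None = None  # default: 1 mean halo diameter
    stain_matrix_id: str = "default"
    background_od_noise: float = 0.02
    duct_radius_um: tuple[float, float] = (30.0, 60.0)
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.eer_fraction <= 1.0):
            raise ValueError("eer_fraction must be in [0, 1]")
        if not (0.0 <= self.pe_fraction_of_eer <= 1.0):
            raise ValueError("pe_fraction_of_eer must be in [0, 1]")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.panel not in PANEL_CLASSES:
            raise ValueError(f"unknown panel {self.panel!r}")
        for (cls, comp), d in self.planted_density.items():
            if d < 0:
                raise ValueError(f"negative density for {(cls, comp)}")
            if cls not in PANEL_CLASSES[self.panel]:
                raise ValueError(f"class {cls!r} not in panel {self.panel!r}")
            if comp not in ("PE", "ILS"):
                raise ValueError("densities are planted in PE or ILS only")

    @property
    def min_separation(self) -> float:
        if self.min_separation_um is not None:
            return self.min_separation_um
        return self.halo_diameter_um[0]


@dataclass
class PlantedObject:
    id: int
    centroid_px: tuple[int, int]  # (row, col)
    diameter_um: float  # chromogen object diameter
    true_class: str
    true_compartment: str  # "PE" | "ILS"
    has_nucleus: bool = True
    chromogens: tuple[str, ...] = ()
    amplitude: float = 1.0
    nucleus_diameter_um: float = 0.0


@dataclass
class GroundTruth:
    compartment_mask: CompartmentMask
    cells: list[PlantedObject]
    speckles: list[PlantedObject]
    debris: list[PlantedObject]
    planted_density_realized: dict[tuple[str, str], float]

    def counts(self) -> dict[tuple[str, str], int]:
        out: dict[tuple[str, str], int] = {}
        for c in self.cells:
            key = (c.true_class, c.true_compartment)
            out[key] = out.get(key, 0) + 1
        return out


# ---------------------------------------------------------------------------
# geometry

def _eer_mask(shape, eer_fraction, rng) -> np.ndarray:
    """Smooth blobby EER mask with (near-)exact area fraction: a Gaussian
    random field thresholded at the matching quantile."""
    n_px = shape[0] * shape[1]
    if eer_fraction <= 0:
        return np.zeros(shape, dtype=bool)
    if eer_fraction >= 1:
        return np.ones(shape, dtype=bool)
    if round(n_px * eer_fraction) < 1:
        raise ValueError("image too small to contain any EER at requested fraction")
    sigma = max(4.0, min(shape) / 10.0)
    # the field is smooth at scale sigma, so draw it on a coarse grid and
    # bilinearly upsample: identical statistics, much cheaper than a
    # full-resolution filter at large sigma
    ds = max(1, int(sigma / 6.0))
    small = (-(-shape[0] // ds) + 1, -(-shape[1] // ds) + 1)
    fld_small = gaussian_filter(rng.standard_normal(small), sigma / ds, mode="reflect")
    fld = zoom(fld_small, ds, order=1)[: shape[0], : shape[1]]
    thr = np.quantile(fld, 1.0 - eer_fraction)
    return fld > thr


def _pe_mask(eer, pe_fraction, duct_radius_um, pixel_size_um, rng) -> np.ndarray:
    """Union of duct/alveolar foci (filled disks, the epithelial band plus
    its immediate rim) grown inside EER until the PE share of EER reaches
    the target fraction."""
    pe = np.zeros_like(eer)
    n_eer = int(np.count_nonzero(eer))
    if n_eer == 0 or pe_fraction <= 0:
        return pe
    if pe_fraction >= 1:
        return eer.copy()
    coords = np.argwhere(eer)
    target = pe_fraction * n_eer
    r_lo, r_hi = duct_radius_um
    rows, cols = eer.shape
    for _ in range(2000):
        if np.count_nonzero(pe) >= target:
            break
        cy, cx = coords[rng.integers(len(coords))]
        r_px = rng.uniform(r_lo, r_hi) / pixel_size_um
        y0, y1 = max(0, int(cy - r_px)), min(rows, int(cy + r_px) + 1)
        x0, x1 = max(0, int(cx - r_px)), min(cols, int(cx + r_px) + 1)
        yy, xx = np.ogrid[y0:y1, x0:x1]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
        pe[y0:y1, x0:x1] |= disk & eer[y0:y1, x0:x1]
    return pe


# ---------------------------------------------------------------------------
# hard-core placement

class _HardCoreGrid:
    """Grid hash for dart-throwing with a minimum pairwise separation."""

    def __init__(self, min_sep_px: float):
        self.sep2 = min_sep_px**2
        self.cell = max(1.0, min_sep_px)
        self.buckets: dict[tuple[int, int], list[tuple[float, float]]] = {}

    def try_add(self, y: float, x: float) -> bool:
        by, bx = int(y // self.cell), int(x // self.cell)
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                for py, px in self.buckets.get((by + dy, bx + dx), ()):
                    if (py - y) ** 2 + (px - x) ** 2 < self.sep2:
                        return False
        self.buckets.setdefault((by, bx), []).append((y, x))
        return True


def _place(coords: np.ndarray, n: int, grid: _HardCoreGrid, rng) -> list[tuple[int, int]]:
    """Place n points among candidate pixel coords under the hard-core
    constraint; raises OvercrowdedSceneError if the candidates are exhausted."""
    if n == 0:
        return []
    order = rng.permutation(len(coords))
    placed: list[tuple[int, int]] = []
    for idx in order:
        y, x = coords[idx]
        if grid.try_add(float(y), float(x)):
            placed.append((int(y), int(x)))
            if len(placed) == n:
                return placed
    raise OvercrowdedSceneError(
        f"overcrowded scene: placed {len(placed)} of {n} requested objects"
    )


# ---------------------------------------------------------------------------
# rendering

def _paint_disk(arr: np.ndarray, cy: int, cx: int, radius_px: float, amount: float) -> None:
    rows, cols = arr.shape
    y0, y1 = max(0, int(cy - radius_px)), min(rows, int(cy + radius_px) + 1)
    x0, x1 = max(0, int(cx - radius_px)), min(cols, int(cx + radius_px) + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.ogrid[y0:y1, x0:x1]
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2
    arr[y0:y1, x0:x1][disk] += amount


def _chromogens_for(cls: str, spec: SceneSpec, rng) -> tuple[str, ...]:
    base = CLASS_CHROMOGEN[cls]
    if cls == "M2" and rng.random() < spec.m2_double_positive_fraction:
        return ("teal", "yellow")  # CD163+/CD68+ double positive, renders green
    return (base,)


def generate_scene(spec: SceneSpec):
    """Render one scene; returns (rgb uint8 image, GroundTruth).

    Deterministic for a fixed spec (including its seed).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_size_px)

    eer = _eer_mask(shape, spec.eer_fraction, rng)
    pe = _pe_mask(eer, spec.pe_fraction_of_eer, spec.duct_radius_um, spec.pixel_size_um, rng)
    labels = np.zeros(shape, dtype=np.uint8)
    labels[eer] = ILS
    labels[pe] = PE
    mask = CompartmentMask(labels=labels, pixel_size_um=spec.pixel_size_um)

    px_area = mask.pixel_area_mm2
    comp_coords = {"PE": np.argwhere(labels == PE), "ILS": np.argwhere(labels == ILS)}
    comp_area = {name: len(comp_coords[name]) * px_area for name in comp_coords}

    grid = _HardCoreGrid(spec.min_separation / spec.pixel_size_um)
    cells: list[PlantedObject] = []
    speckles: list[PlantedObject] = []
    debris: list[PlantedObject] = []
    next_id = 0

    def draw_halo_diam() -> float:
        d = rng.normal(*spec.halo_diameter_um)
        return max(d, spec.halo_min_um)

    # cells, in sorted key order for determinism
    for (cls, comp) in sorted(spec.planted_density):
        dens = spec.planted_density[(cls, comp)]
        lam = dens * comp_area[comp]
        n = int(rng.poisson(lam)) if lam > 0 else 0
        if n > 0 and len(comp_coords[comp]) == 0:
            raise OvercrowdedSceneError(f"no {comp} pixels to plant {cls} cells in")
        for (y, x) in _place(comp_coords[comp], n, grid, rng):
            cells.append(
                PlantedObject(
                    id=next_id,
                    centroid_px=(y, x),
                    diameter_um=draw_halo_diam(),
                    true_class=cls,
                    true_compartment=comp,
                    has_nucleus=True,
                    chromogens=_chromogens_for(cls, spec, rng),
                    amplitude=max(1.0, rng.normal(*spec.chromogen_amplitude)),
                    nucleus_diameter_um=float(np.clip(rng.normal(*spec.cell_diameter_um), *spec.nucleus_diameter_clip_um)),
                )
            )
            next_id += 1

    # nucleus-free CD68 speckles (fragments of sliced macrophages)
    if spec.cd68_speckle_fraction > 0:
        cd68_classes = [c for c in PANEL_CLASSES[spec.panel] if CLASS_CHROMOGEN[c] == "yellow"]
        for (cls, comp) in sorted(spec.planted_density):
            if cls not in cd68_classes:
                continue
            lam = spec.cd68_speckle_fraction * spec.planted_density[(cls, comp)] * comp_area[comp]
            n = int(rng.poisson(lam)) if lam > 0 else 0
            for (y, x) in _place(comp_coords[comp], n, grid, rng):
                speckles.append(
                    PlantedObject(
                        id=next_id,
                        centroid_px=(y, x),
                        diameter_um=draw_halo_diam(),
                        true_class="speckle",
                        true_compartment=comp,
                        has_nucleus=False,
                        chromogens=("yellow",),
                        amplitude=max(1.0, rng.normal(*spec.chromogen_amplitude)),
                    )
                )
                next_id += 1

    # sub-15-um debris, spread over all of EER, cycling through the panel's chromogens
    if spec.debris_per_mm2 > 0:
        eer_coords = np.argwhere(labels != FSR)
        lam = spec.debris_per_mm2 * len(eer_coords) * px_area
        n = int(rng.poisson(lam)) if lam > 0 else 0
        chroms = sorted({CLASS_CHROMOGEN[c] for c in PANEL_CLASSES[spec.panel]})
        for i, (y, x) in enumerate(_place(eer_coords, n, grid, rng)):
            d = float(np.clip(rng.normal(*spec.debris_diameter_um), 3.0, 13.0))
            debris.append(
                PlantedObject(
                    id=next_id,
                    centroid_px=(y, x),
                    diameter_um=d,
                    true_class="debris",
                    true_compartment=LABEL_NAMES[labels[y, x]],
                    has_nucleus=False,
                    chromogens=(chroms[i % len(chroms)],),
                    amplitude=max(1.0, rng.normal(*spec.chromogen_amplitude)),
                )
            )
            next_id += 1

    # --- concentration fields -> OD -> RGB
    registry = load_stain_registry()
    conc = {name: np.zeros(shape, dtype=float) for name in registry}
    for lab, level in BACKGROUND_HEMATOXYLIN.items():
        conc["hematoxylin"][labels == lab] = level

    for obj in cells + speckles + debris:
        cy, cx = obj.centroid_px
        r_px = obj.diameter_um / 2.0 / spec.pixel_size_um
        for ch in obj.chromogens:
            _paint_disk(conc[ch], cy, cx, r_px, obj.amplitude)
        if obj.has_nucleus:
            rn = obj.nucleus_diameter_um / 2.0 / spec.pixel_size_um
            _paint_disk(conc["hematoxylin"], cy, cx, rn, spec.nucleus_amplitude)

    od = np.zeros(shape + (3,), dtype=np.float32)
    for name, c in conc.items():
        if np.any(c):
            od += c[..., None] * registry[name][None, None, :]
    if spec.background_od_noise > 0:
        od += rng.normal(0.0, spec.background_od_noise, size=od.shape).astype(np.float32)
    od = np.clip(od, 0.0, None)
    rgb = od_to_rgb(od)

    realized = {}
    counts: dict[tuple[str, str], int] = {}
    for c in cells:
        counts[(c.true_class, c.true_compartment)] = counts.get((c.true_class, c.true_compartment), 0) + 1
    for key in sorted(set(spec.planted_density) | set(counts)):
        area = comp_area[key[1]]
        realized[key] = counts.get(key, 0) / area if area > 0 else math.nan

    truth = GroundTruth(
        compartment_mask=mask,
        cells=cells,
        speckles=speckles,
        debris=debris,
        planted_density_realized=realized,
    )
    return rgb, truth
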