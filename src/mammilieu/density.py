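"""Cell densities per donor, class, and tissue compartment.

Density is defined as count / area (cells per mm^2) within the compartment
the cells localize to.  Donor-level densities pool counts and areas across
that donor's images before dividing (never an average of per-image
densities), so EER_total density is (count_PE + count_ILS) /
(area_PE + area_ILS) by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from mammilieu.masks import ILS, PE, CompartmentMask
from mammilieu.detection import DetectedCell

__all__ = ["DensityRecord", "compute_density", "pool_density_records", "records_to_frame"]

COMPARTMENTS = ("PE", "ILS", "EER_total")


@dataclass
class DensityRecord:
    donor_id: str
    panel: str
    cell_class: str
    compartment: str  # "PE" | "ILS" | "EER_total"
    count: int
    area_mm2: float
    density: float  # cells per mm^2, count / area exactly


def _make_record(donor_id, panel, cls, comp, count, area) -> DensityRecord | None:
    if area <= 0:
        if count > 0:
            raise ValueError(
                f"compartment {comp} has zero area but {count} cells: inconsistent inputs"
            )
        warnings.warn(f"compartment {comp} has zero area; record omitted", stacklevel=3)
        return None
    return DensityRecord(donor_id, panel, cls, comp, count, area, count / area)


def compute_density(
    cells: list[DetectedCell],
    mask: CompartmentMask,
    donor_id: str,
    panel: str = "triple",
    classes: tuple[str, ...] | None = None,
) -> list[DensityRecord]:
    """Density records for one image: each class x {PE, ILS, EER_total}.

    Cells with compartment "outside" (centroid in FSR) are not counted.
    """
    from mammilieu.simulate.scene import PANEL_CLASSES  # class roster per panel

    if classes is None:
        classes = PANEL_CLASSES[panel]
    area = {"PE": mask.area_mm2(PE), "ILS": mask.area_mm2(ILS)}
    area["EER_total"] = area["PE"] + area["ILS"]
    records: list[DensityRecord] = []
    for cls in classes:
        n = {"PE": 0, "ILS": 0}
        for cell in cells:
            if cell.cell_class == cls and cell.compartment in n:
                n[cell.compartment] += 1
        counts = {"PE": n["PE"], "ILS": n["ILS"], "EER_total": n["PE"] + n["ILS"]}
        for comp in COMPARTMENTS:
            rec = _make_record(donor_id, panel, cls, comp, counts[comp], area[comp])
            if rec is not None:
                records.append(rec)
    return records


def pool_density_records(records: list[DensityRecord]) -> list[DensityRecord]:
    """Pool per-image records into donor-level ones by summing counts and
    areas per (donor, panel, class, compartment), then dividing."""
    acc: dict[tuple[str, str, str, str], list[float]] = {}
    for r in records:
        key = (r.donor_id, r.panel, r.cell_class, r.compartment)
        cur = acc.setdefault(key, [0, 0.0])
        cur[0] += r.count
        cur[1] += r.area_mm2
    out = []
    for (donor, panel, cls, comp), (count, area) in sorted(acc.items()):
        rec = _make_record(donor, panel, cls, comp, int(count), area)
        if rec is not None:
            out.append(rec)
    return out


def records_to_frame(records: list[DensityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "donor_id": r.donor_id,
                "panel": r.panel,
                "cell_class": r.cell_class,
                "compartment": r.compartment,
                "count": r.count,
                "area_mm2": r.area_mm2,
                "density": r.density,
            }
            for r in records
        ]
    )
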