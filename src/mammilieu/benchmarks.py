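"""Parameter-recovery benchmarks shared by the test suite and the
acceptance script.

Each benchmark regenerates its inputs from a seed, runs the relevant part
of the pipeline, and returns the measured quantity:

* planted-density recovery: cells planted uniformly at a given density in
  one compartment over at least a minimum total area, recovered through
  oracle segmentation + detection + quantification (counts and areas
  pooled across scenes before dividing);
* flow CD45 recovery: synthetic filtrate events gated for viability and
  CD45, returning the CD45 percentage of viable events;
* stage-B segmenter training: validation pixel error after training the
  desk-scale encoder-decoder on synthetic annotated tiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from mammilieu.detection import DetectionParams, assign_compartment, detect_scene
from mammilieu.density import compute_density, pool_density_records
from mammilieu.gating import gate_subsets, gate_viable
from mammilieu.segmentation import (
    TrainParams,
    oracle_segmenter,
    tiles_from_scene,
    train_segmenter,
)
from mammilieu.simulate.flow import FlowProfile, generate_flow_events
from mammilieu.simulate.scene import CLASS_CHROMOGEN, SceneSpec, generate_scene

__all__ = [
    "DensityRecovery",
    "recover_planted_density",
    "flow_cd45_recovery",
    "stage_b_validation_error",
]

#: marker whose chromogen carries each triple-panel class
_CLASS_MARKER = {"T": "CD3", "B": "CD20", "Mac": "CD68"}

#: scene geometry used for recovery runs: mostly-EER fields so the target
#: compartment dominates the image
_SCENE_PX = (1792, 1792)


@dataclass
class DensityRecovery:
    planted_density: float
    recovered_density: float
    pooled_area_mm2: float
    n_scenes: int
    n_planted: int
    n_detected: int

    @property
    def relative_error(self) -> float:
        return (self.recovered_density - self.planted_density) / self.planted_density


def recover_planted_density(
    density: float,
    compartment: str,
    seed: int,
    cell_class: str = "Mac",
    speckle_fraction: float = 0.0,
    min_area_mm2: float = 10.0,
) -> DensityRecovery:
    """Plant ``density`` cells/mm^2 of one class in one compartment over at
    least ``min_area_mm2`` of tissue (pooled over scenes) and measure the
    density the pipeline recovers with oracle segmentation."""
    if compartment not in ("PE", "ILS"):
        raise ValueError("compartment must be PE or ILS")
    if compartment == "ILS":
        eer_fraction, pe_fraction = 0.95, 0.05
    else:
        eer_fraction, pe_fraction = 0.95, 0.90
    px_area_mm2 = _SCENE_PX[0] * _SCENE_PX[1] * (0.465e-3) ** 2
    useful = px_area_mm2 * eer_fraction * (pe_fraction if compartment == "PE" else 1 - pe_fraction)
    # 5% headroom: realized compartment areas run slightly under the
    # nominal fractions (duct foci overshoot, quantile rounding)
    n_scenes = max(1, math.ceil(min_area_mm2 / (0.95 * useful)))

    params = DetectionParams()
    records = []
    n_planted = 0
    for k in range(n_scenes):
        spec = SceneSpec(
            image_size_px=_SCENE_PX,
            eer_fraction=eer_fraction,
            pe_fraction_of_eer=pe_fraction,
            planted_density={(cell_class, compartment): density},
            cd68_speckle_fraction=speckle_fraction,
            seed=seed * 1000 + k,
        )
        rgb, truth = generate_scene(spec)
        n_planted += len(truth.cells)
        mask = oracle_segmenter(truth)
        cells = detect_scene(rgb, params, panel="triple", markers=[_CLASS_MARKER[cell_class]])
        cells = assign_compartment(cells, mask)
        records.extend(compute_density(cells, mask, "pooled", classes=(cell_class,)))
    pooled = {r.compartment: r for r in pool_density_records(records)}
    rec = pooled[compartment]
    return DensityRecovery(
        planted_density=density,
        recovered_density=rec.density,
        pooled_area_mm2=rec.area_mm2,
        n_scenes=n_scenes,
        n_planted=n_planted,
        n_detected=rec.count,
    )


def flow_cd45_recovery(seed: int, cd45_fraction: float = 0.11, n_events: int = 60_000) -> dict:
    """Generate filtrate events at a planted CD45 fraction of viable
    mononuclear events and return the gated CD45 percentage."""
    profile = FlowProfile(n_events=n_events, cd45_fraction=cd45_fraction, seed=seed)
    viable = gate_viable(generate_flow_events(profile))
    res = gate_subsets(viable)
    return {
        "planted_pct": 100.0 * cd45_fraction,
        "gated_pct": float(res["cd45_pct_of_viable"]),
        "n_viable": len(viable),
    }


def stage_b_validation_error(
    seed: int, n_scenes: int = 4, max_epochs: int = 60
) -> float:
    """Train the desk-scale stage-B (PE vs ILS) segmenter on synthetic
    annotated tiles and return the held-out validation pixel error."""
    rng = np.random.default_rng(seed)
    xs, ys, ws = [], [], []
    for k in range(n_scenes):
        spec = SceneSpec(
            image_size_px=(448, 448),
            eer_fraction=0.55,
            pe_fraction_of_eer=0.35,
            seed=seed * 100 + k,
        )
        rgb, truth = generate_scene(spec)
        a, b, c = tiles_from_scene(rgb, truth.compartment_mask, "B", tile=64, max_tiles=10, rng=rng)
        xs += a
        ys += b
        ws += c
    model = train_segmenter(xs, ys, "B", TrainParams(max_epochs=max_epochs, seed=seed), weights=ws)
    return model.validation_error
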