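"""Two-stage semantic tissue segmentation.

Stage A separates epithelium-enriched regions (EER) from fat/stroma (FSR)
over the whole image; stage B runs only inside the stage-A EER mask and
splits it into peri-epithelium (PE) and intralobular stroma (ILS).  The
two-stage design restricts the harder PE/ILS decision to tissue that is
already known to be epithelium-enriched.

Both stages share one encoder-decoder family (:mod:`mammilieu.unet`);
training stops when the validation pixel error drops below the target
(default 10%) or the epoch budget is exhausted, in which case the model is
returned with ``converged = False`` and a warning.  "Validation error" is
the fraction of misclassified pixels on held-out tiles, restricted to EER
pixels for stage B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import remove_small_holes, remove_small_objects

from mammilieu.masks import FSR, ILS, PE, CompartmentMask
from mammilieu.unet import TinyUNet, softmax_cross_entropy

__all__ = [
    "TrainParams",
    "SegmenterModel",
    "train_segmenter",
    "segment_eer",
    "segment_pe_ils",
    "oracle_segmenter",
    "tiles_from_scene",
]


@dataclass
class TrainParams:
    """Desk-scale training configuration.

    tile is the network input size (the full-scale reference uses 512x512;
    smaller tiles are supported down to 2**depth).  target_error is the
    stopping criterion on held-out pixel error; max_epochs bounds the
    budget.
    """

    tile: int = 64
    base_channels: int = 8
    depth: int = 2
    lr: float = 3e-3
    max_epochs: int = 60
    target_error: float = 0.10
    val_fraction: float = 0.25
    augment: bool = True
    intensity_jitter: float = 0.08
    seed: int = 0

    def validate(self) -> None:
        if self.tile % 2**self.depth != 0:
            raise ValueError("tile size must be divisible by 2**depth")
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in (0, 1)")


@dataclass
class SegmenterModel:
    """Trained weights plus the metadata needed to apply them."""

    stage: str  # "A" (EER vs FSR) or "B" (PE vs ILS inside EER)
    net: TinyUNet
    tile: int
    validation_error: float
    converged: bool = True
    history: list[float] = field(default_factory=list)

    def save(self, path) -> None:
        state = self.net.state_dict()
        state["stage"] = np.array(self.stage)
        state["tile"] = np.array(self.tile)
        state["validation_error"] = np.array(self.validation_error)
        state["converged"] = np.array(self.converged)
        np.savez(path, **state)

    @classmethod
    def load(cls, path) -> "SegmenterModel":
        state = dict(np.load(path, allow_pickle=False))
        return cls(
            stage=str(state.pop("stage")),
            tile=int(state.pop("tile")),
            validation_error=float(state.pop("validation_error")),
            converged=bool(state.pop("converged")),
            net=TinyUNet.from_state(state),
        )


def _as_float_image(img: np.ndarray) -> np.ndarray:
    x = np.asarray(img, dtype=float)
    if x.max() > 1.5:
        x = x / 255.0
    return np.moveaxis(x, -1, 0)  # (3, H, W)


def _augment(x, y, w, rng, jitter):
    if rng.random() < 0.5:
        x, y, w = x[:, :, ::-1], y[:, ::-1], w[:, ::-1]
    if rng.random() < 0.5:
        x, y, w = x[:, ::-1, :], y[::-1, :], w[::-1, :]
    k = int(rng.integers(4))
    if k:
        x = np.rot90(x, k, axes=(1, 2))
        y = np.rot90(y, k)
        w = np.rot90(w, k)
    if jitter > 0:
        x = np.clip(x * (1.0 + rng.uniform(-jitter, jitter)), 0.0, 1.2)
    return np.ascontiguousarray(x), np.ascontiguousarray(y), np.ascontiguousarray(w)


def _error(net, xs, ys, ws) -> float:
    bad = tot = 0.0
    for x, y, w in zip(xs, ys, ws):
        pred = np.argmax(net.predict_proba(x), axis=0)
        bad += float(((pred != y) * (w > 0)).sum())
        tot += float((w > 0).sum())
    return bad / tot if tot > 0 else 0.0


def train_segmenter(
    tiles: list[np.ndarray],
    label_masks: list[np.ndarray],
    stage: str,
    params: TrainParams | None = None,
    weights: list[np.ndarray] | None = None,
) -> SegmenterModel:
    """Train one stage on annotated tiles.

    tiles: RGB arrays (H, W, 3); label_masks: int arrays (H, W) with the
    stage's binary classes (stage A: 1 = EER, 0 = FSR; stage B: 1 = PE,
    0 = ILS).  ``weights`` (optional, same shapes) excludes pixels from the
    loss and the error — stage B passes the EER mask here so FSR pixels
    never influence the PE/ILS decision.
    """
    params = params or TrainParams()
    params.validate()
    if stage not in ("A", "B"):
        raise ValueError("stage must be 'A' or 'B'")
    if len(tiles) < 2:
        raise ValueError("need at least two annotated tiles")
    xs = [_as_float_image(t) for t in tiles]
    ys = [np.asarray(m).astype(np.int64) for m in label_masks]
    ws = (
        [np.asarray(w, dtype=float) for w in weights]
        if weights is not None
        else [np.ones_like(y, dtype=float) for y in ys]
    )
    seen = set()
    for y, w in zip(ys, ws):
        seen |= set(np.unique(y[w > 0]).tolist())
    if len(seen) < 2:
        raise ValueError("training data contains a single class; cannot train")

    rng = np.random.default_rng(params.seed)
    n_val = max(1, int(round(params.val_fraction * len(xs))))
    order = rng.permutation(len(xs))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        raise ValueError("no tiles left for training after validation split")

    net = TinyUNet(
        in_ch=3, n_classes=2, base=params.base_channels, depth=params.depth,
        lr=params.lr, seed=params.seed,
    )
    xv = [xs[i] for i in val_idx]
    yv = [ys[i] for i in val_idx]
    wv = [ws[i] for i in val_idx]

    history: list[float] = []
    val_err = 1.0
    for _ in range(params.max_epochs):
        for i in rng.permutation(train_idx):
            x, y, w = xs[i], ys[i], ws[i]
            if params.augment:
                x, y, w = _augment(x, y, w, rng, params.intensity_jitter)
            logits = net.forward(x)
            _, grad = softmax_cross_entropy(logits, y, w)
            net.backward(grad)
        val_err = _error(net, xv, yv, wv)
        history.append(val_err)
        if val_err < params.target_error:
            break
    converged = val_err < params.target_error
    if not converged:
        warnings.warn(
            f"stage-{stage} segmenter did not reach target error "
            f"{params.target_error:.2f} (validation error {val_err:.3f})"
        )
    return SegmenterModel(
        stage=stage, net=net, tile=params.tile,
        validation_error=val_err, converged=converged, history=history,
    )


def _stitched_proba(image: np.ndarray, model: SegmenterModel) -> np.ndarray:
    """Tile-and-stitch inference with 50% overlap and averaged class
    scores; images smaller than one tile are padded and cropped back."""
    x = _as_float_image(image)
    _, h, w = x.shape
    t = model.tile
    ph, pw = max(t, int(np.ceil(h / t)) * t), max(t, int(np.ceil(w / t)) * t)
    xp = np.pad(x, ((0, 0), (0, ph - h), (0, pw - w)), mode="reflect")
    proba = np.zeros((model.net.n_classes, ph, pw))
    hits = np.zeros((ph, pw))
    step = t // 2
    for y0 in range(0, ph - t + 1, step):
        for x0 in range(0, pw - t + 1, step):
            p = model.net.predict_proba(xp[:, y0 : y0 + t, x0 : x0 + t])
            proba[:, y0 : y0 + t, x0 : x0 + t] += p
            hits[y0 : y0 + t, x0 : x0 + t] += 1
    return (proba / hits)[:, :h, :w]


def segment_eer(
    image: np.ndarray,
    model: SegmenterModel,
    min_region_px: int = 256,
    fill_holes_px: int = 256,
) -> np.ndarray:
    """Stage A: binary EER mask with morphological cleanup."""
    if model.stage != "A":
        raise ValueError("segment_eer requires a stage-A model")
    proba = _stitched_proba(image, model)
    eer = np.argmax(proba, axis=0) == 1
    if min_region_px > 0:
        eer = remove_small_objects(eer, max_size=min_region_px - 1)
    if fill_holes_px > 0:
        eer = remove_small_holes(eer, max_size=fill_holes_px - 1)
    return eer


def segment_pe_ils(
    image: np.ndarray,
    eer_mask: np.ndarray,
    model: SegmenterModel,
    pixel_size_um: float = 0.465,
    min_region_px: int = 64,
) -> CompartmentMask:
    """Stage B: assign PE vs ILS inside the EER mask only; everything
    outside stays FSR."""
    if model.stage != "B":
        raise ValueError("segment_pe_ils requires a stage-B model")
    eer = np.asarray(eer_mask, dtype=bool)
    labels = np.zeros(eer.shape, dtype=np.uint8)
    if not eer.any():
        warnings.warn("empty EER mask: returning all-FSR compartment mask")
        return CompartmentMask(labels=labels, pixel_size_um=pixel_size_um)
    proba = _stitched_proba(image, model)
    pe = np.argmax(proba, axis=0) == 1
    if min_region_px > 0:
        pe = remove_small_objects(pe, max_size=min_region_px - 1) | ~(
            remove_small_objects(~pe, max_size=min_region_px - 1)
        )
    labels[eer] = ILS
    labels[eer & pe] = PE
    return CompartmentMask(labels=labels, pixel_size_um=pixel_size_um)


def oracle_segmenter(ground_truth) -> CompartmentMask:
    """Return the generator's true compartment mask verbatim, decoupling
    detection/quantification tests from segmentation quality."""
    src = ground_truth.compartment_mask
    return CompartmentMask(labels=src.labels.copy(), pixel_size_um=src.pixel_size_um)


def tiles_from_scene(
    rgb: np.ndarray,
    mask: CompartmentMask,
    stage: str,
    tile: int = 64,
    max_tiles: int = 32,
    rng: np.random.Generator | None = None,
    min_weight_fraction: float = 0.05,
) -> tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray]]:
    """Cut (tile, label, weight) training triples out of a rendered scene.

    Stage A: label 1 = EER; all pixels weighted.  Stage B: label 1 = PE,
    0 = ILS, weight = EER mask; tiles with almost no EER are skipped.
    """
    rng = rng or np.random.default_rng(0)
    h, w = mask.shape
    xs, ys, ws = [], [], []
    tries = 0
    while len(xs) < max_tiles and tries < max_tiles * 20:
        tries += 1
        y0 = int(rng.integers(0, max(1, h - tile + 1)))
        x0 = int(rng.integers(0, max(1, w - tile + 1)))
        lab = mask.labels[y0 : y0 + tile, x0 : x0 + tile]
        if lab.shape != (tile, tile):
            continue
        if stage == "A":
            target = (lab != FSR).astype(np.int64)
            weight = np.ones_like(target, dtype=float)
        else:
            target = (lab == PE).astype(np.int64)
            weight = (lab != FSR).astype(float)
            if weight.mean() < min_weight_fraction:
                continue
        xs.append(rgb[y0 : y0 + tile, x0 : x0 + tile])
        ys.append(target)
        ws.append(weight)
    return xs, ys, ws
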