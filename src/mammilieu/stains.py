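"""Optical-density color deconvolution for brightfield chromogens.

Brightfield stains attenuate light according to Beer-Lambert, so stain
amounts combine (approximately) linearly in optical-density space:

    OD = -log10(I_transmitted / I_incident) = M @ c

where the columns of ``M`` are unit "stain vectors" (the RGB absorption
signature of each chromogen) and ``c`` the per-stain concentrations.
Unmixing is the pseudo-inverse of ``M`` applied per pixel.

A deconvolution pass handles at most three stains.  Multiplex panels with
more chromogens are unmixed one marker at a time against the hematoxylin
counterstain plus a residual vector orthogonal to both, which is exact for
the marker and counterstain and leaves the remaining chromogens projected
onto the residual (their positive leakage into the marker channel is small
for the shipped vectors; negative leakage is clipped downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "StainMatrix",
    "ChannelStack",
    "load_stain_registry",
    "marker_pass_matrix",
    "rgb_to_od",
    "od_to_rgb",
    "deconvolve",
    "channel_to_intensity",
    "intensity_to_concentration",
]

#: Upper bound of the OD transform: a pixel value of 0 maps to log10(256).
OD_MAX = float(np.log10(256.0))

_COND_LIMIT = 1e6


@dataclass(frozen=True)
class StainMatrix:
    """Ordered set of unit stain vectors defining one deconvolution pass."""

    stain_names: tuple[str, ...]
    vectors: np.ndarray  # shape (3, n_stains), columns are unit OD vectors
    matrix_id: str = "unnamed"

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.shape != (3, len(self.stain_names)):
            raise ValueError(
                f"vectors shape {v.shape} does not match {len(self.stain_names)} stains"
            )
        norms = np.linalg.norm(v, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain vectors must have unit Euclidean norm")
        object.__setattr__(self, "vectors", v)
        if np.linalg.cond(self.padded()) > _COND_LIMIT:
            raise ValueError("collinear stains: deconvolution ill-conditioned")

    @property
    def n_stains(self) -> int:
        return len(self.stain_names)

    def padded(self) -> np.ndarray:
        """Return a full-rank 3x3 matrix, padding with a residual vector
        orthogonal to the given stains when fewer than three are present."""
        v = self.vectors
        if v.shape[1] == 3:
            return v
        if v.shape[1] == 2:
            r = np.cross(v[:, 0], v[:, 1])
            n = np.linalg.norm(r)
            if n < 1e-12:
                raise ValueError("collinear stains: cannot build residual vector")
            return np.column_stack([v, r / n])
        if v.shape[1] == 1:
            # any orthonormal completion
            q, _ = np.linalg.qr(np.column_stack([v, np.eye(3)]))
            return q[:, :3] * np.sign(np.sum(q[:, :1] * v))
        raise ValueError("StainMatrix needs 1-3 stains")

    def index(self, name: str) -> int:
        return self.stain_names.index(name)


@dataclass
class ChannelStack:
    """Per-stain concentration maps produced by one deconvolution pass."""

    stain_names: tuple[str, ...]
    concentrations: np.ndarray  # shape (n_stains, rows, cols)
    matrix_id: str
    reconstruction_rmse: float = 0.0
    extras: dict = field(default_factory=dict)

    def channel(self, name: str) -> np.ndarray:
        return self.concentrations[self.stain_names.index(name)]


def load_stain_registry(path=None) -> dict[str, np.ndarray]:
    """Load the named stain vectors (unit OD 3-vectors) from the YAML registry.

    With no path the registry shipped with the package is used.
    """
    if path is None:
        text = resources.files("mammilieu.data").joinpath("stains.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    reg = {}
    for name, vec in raw["stains"].items():
        v = np.asarray(vec, dtype=float)
        reg[name] = v / np.linalg.norm(v)
    return reg


def marker_pass_matrix(
    marker: str, registry: dict[str, np.ndarray] | None = None
) -> StainMatrix:
    """Build the single-marker deconvolution pass: marker + hematoxylin +
    residual vector orthogonal to both."""
    reg = registry if registry is not None else load_stain_registry()
    m, h = reg[marker], reg["hematoxylin"]
    r = np.cross(m, h)
    r /= np.linalg.norm(r)
    return StainMatrix(
        stain_names=(marker, "hematoxylin", "residual"),
        vectors=np.column_stack([m, h, r]),
        matrix_id=f"{marker}+hematoxylin",
    )


def rgb_to_od(image: np.ndarray) -> np.ndarray:
    """Map 8-bit RGB intensities to optical density, OD = -log10((I+1)/256).

    The +1 offset keeps OD finite at I = 0 (OD_MAX ~ 2.408); I = 255 maps
    to exactly 0 (blank background).
    """
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")
    if img.min() < 0 or img.max() > 255:
        raise ValueError("image channels must lie in [0, 255]")
    return -np.log10((img + 1.0) / 256.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`, quantized to uint8."""
    i = 256.0 * np.power(10.0, -np.asarray(od, dtype=float)) - 1.0
    return np.clip(np.round(i), 0, 255).astype(np.uint8)


def deconvolve(od_image: np.ndarray, matrix: StainMatrix) -> ChannelStack:
    """Unmix an OD image (rows, cols, 3) into per-stain concentration maps.

    Concentrations are the pseudo-inverse of the (padded) stain matrix
    applied to every pixel's OD vector; the root-mean-square reconstruction
    residual |OD - M c| is recorded on the returned stack.
    """
    od = np.asarray(od_image, dtype=float)
    if od.ndim != 3 or od.shape[2] != 3:
        raise ValueError("od_image must have shape (rows, cols, 3)")
    full = matrix.padded()
    if np.linalg.cond(full) > _COND_LIMIT:
        raise ValueError("collinear stains")
    pinv = np.linalg.pinv(full)
    flat = od.reshape(-1, 3)
    conc = flat @ pinv.T  # (n_px, 3)
    resid = flat - conc @ full.T
    rmse = float(np.sqrt(np.mean(resid**2)))
    names = tuple(matrix.stain_names)
    if len(names) < 3:
        names = names + tuple(
            f"residual{k}" for k in range(3 - len(names))
        )
    conc = conc.T.reshape(3, od.shape[0], od.shape[1])
    return ChannelStack(
        stain_names=names,
        concentrations=conc,
        matrix_id=matrix.matrix_id,
        reconstruction_rmse=rmse,
    )


def channel_to_intensity(channel: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """Map a concentration channel to the 0-255 intensity convention in which
    0 is the strongest stain: I = 255 * 10**(-c / scale).

    Negative concentrations (deconvolution noise) clip to blank (255).  The
    per-object positivity threshold (< 50) is applied in this space.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    c = np.clip(np.asarray(channel, dtype=float), 0.0, None)
    return 255.0 * np.power(10.0, -c / scale)


def intensity_to_concentration(intensity: float | np.ndarray, scale: float = 1.0) -> np.ndarray:
    """Inverse of :func:`channel_to_intensity` (for threshold bookkeeping)."""
    i = np.clip(np.asarray(intensity, dtype=float), 1e-12, 255.0)
    return -scale * np.log10(i / 255.0)
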