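"""Second-moment structure tensor, coherence scoring and channel selection.

The structure tensor at a pixel is the Gaussian-windowed second-moment
matrix of Gaussian-derivative responses,

    sT = [[Txx, Txy],
          [Txy, Tyy]],

with Txx = g * (phi_x)^2, Tyy = g * (phi_y)^2 and Txy = g * (phi_x phi_y),
where phi_x, phi_y are Gaussian-derivative responses at scale sigma_d and
g is a Gaussian window at scale sigma_w. Its eigen-structure encodes
local orientation: horizontally layered structure (OCT retinal layers)
concentrates energy in Tyy, while vessels of arbitrary orientation are
captured by fusing Txx and Tyy (TMAX). Coherence
c = ((l1 - l2) / (l1 + l2))^2 is 1 on line-like structure and 0 on
isotropic regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import feature

from .scan_io import RetinalScan


@dataclass
class StructureTensorField:
    """Per-pixel components Txx, Tyy (squared-derivative energies) and Txy."""

    txx: np.ndarray
    tyy: np.ndarray
    txy: np.ndarray
    sigma_d: float
    sigma_w: float

    def __post_init__(self) -> None:
        if not (self.txx.shape == self.tyy.shape == self.txy.shape):
            raise ValueError("tensor component grids must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.txx.shape


@dataclass
class CoherenceSummary:
    """Per-pixel coherence plus a coherence-weighted energy score per channel."""

    c: np.ndarray
    channel_scores: dict[str, float]

    def most_coherent_channel(self) -> str:
        return max(self.channel_scores, key=self.channel_scores.get)


def _image_axes_gradients(img: np.ndarray, sigma_d: float) -> tuple[np.ndarray, np.ndarray]:
    # phi_x: derivative along image x (columns, axis 1); phi_y along rows.
    phi_x = gaussian_filter(img, sigma_d, order=(0, 1), mode="reflect")
    phi_y = gaussian_filter(img, sigma_d, order=(1, 0), mode="reflect")
    return phi_x, phi_y


def compute_structure_tensor(
    denoised: RetinalScan | np.ndarray, sigma_d: float = 1.0, sigma_w: float = 3.0
) -> StructureTensorField:
    """Compute the second-moment structure tensor of a grayscale scan."""
    if sigma_d <= 0 or sigma_w <= 0:
        raise ValueError("sigma_d and sigma_w must be positive")
    img = denoised.gray() if isinstance(denoised, RetinalScan) else np.asarray(denoised, float)
    if img.ndim != 2:
        raise ValueError("structure tensor expects a grayscale grid")
    phi_x, phi_y = _image_axes_gradients(img, sigma_d)
    txx = gaussian_filter(phi_x * phi_x, sigma_w, mode="reflect")
    tyy = gaussian_filter(phi_y * phi_y, sigma_w, mode="reflect")
    txy = gaussian_filter(phi_x * phi_y, sigma_w, mode="reflect")
    # clamp tiny negative round-off on the diagonal energies
    txx = np.maximum(txx, 0.0)
    tyy = np.maximum(tyy, 0.0)
    return StructureTensorField(txx=txx, tyy=tyy, txy=txy, sigma_d=sigma_d, sigma_w=sigma_w)


def tensor_eigenvalues(field: StructureTensorField) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form eigenvalues l1 >= l2 of the per-pixel 2x2 tensor."""
    tr = field.txx + field.tyy
    disc = np.sqrt((field.txx - field.tyy) ** 2 + 4.0 * field.txy ** 2)
    l1 = 0.5 * (tr + disc)
    l2 = 0.5 * (tr - disc)
    return l1, l2


def coherence(field: StructureTensorField) -> CoherenceSummary:
    """Per-pixel coherence and the per-channel coherence-weighted energy scores."""
    l1, l2 = tensor_eigenvalues(field)
    s = l1 + l2
    c = np.zeros_like(s)
    nz = s > 0
    c[nz] = ((l1[nz] - l2[nz]) / s[nz]) ** 2
    c = np.clip(c, 0.0, 1.0)
    scores = {
        name: float(np.mean(c * np.abs(grid)))
        for name, grid in (("txx", field.txx), ("tyy", field.tyy), ("txy", field.txy))
    }
    return CoherenceSummary(c=c, channel_scores=scores)


def _rescale01(grid: np.ndarray) -> np.ndarray:
    peak = grid.max()
    if peak <= 0:
        return np.zeros_like(grid)
    return grid / peak


def select_tensor(field: StructureTensorField, mode: str) -> np.ndarray:
    """Select/fuse the tensor channel carrying the finding of interest.

    ``oct_layers``: retinal layers are horizontally oriented, so the
    vertical-derivative energy Tyy is the most coherent channel.
    ``fundus_vessels``: vessels run in every direction, so the TMAX
    fusion max(Txx, Tyy) keeps the strongest response of either
    orientation. Both are rescaled to [0, 1].
    """
    if mode == "oct_layers":
        return _rescale01(field.tyy)
    if mode == "fundus_vessels":
        return _rescale01(np.maximum(field.txx, field.tyy))
    raise ValueError(f"unknown tensor selection mode {mode!r}")


def canny_edges(response: np.ndarray, low: float = 0.1, high: float = 0.3,
                sigma: float = 1.0) -> np.ndarray:
    """Canny edge map of a [0, 1] response grid (hysteresis low/high)."""
    if not (0 <= low < high <= 1):
        raise ValueError("thresholds must satisfy 0 <= low < high <= 1")
    response = np.asarray(response, float)
    return feature.canny(response, sigma=sigma, low_threshold=low, high_threshold=high)
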