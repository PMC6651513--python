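"""Fundus/FA analysis: blood vessels, optic disc, hard exudates.

Vessels are thin dark structures with strong tensor response in every
orientation, so segmentation runs hysteresis thresholding on the TMAX
fusion response, keeps only pixels darker than the field-of-view
background (the tensor response is several pixels wider than the vessel
itself), and drops short components. The optic disc is the brightest
disc-shaped region; hard exudates are small bright blobs found by
top-hat enhancement with the vessel mask and the dilated disc region
excluded.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.ndimage import uniform_filter
from scipy.signal import fftconvolve
from skimage import filters, measure, morphology

from .oct_analysis import FindingMasks
from .scan_io import RetinalScan


def field_of_view_mask(gray: np.ndarray, floor: float = 0.02, erode: int = 5) -> np.ndarray:
    """Circular field of view: non-black pixels, eroded to drop the rim."""
    fov = gray > floor
    if erode > 0:
        fov = morphology.erosion(fov, morphology.disk(erode))
    return fov


def extract_vessels(
    response: np.ndarray,
    low: float = 0.05,
    high: float = 0.20,
    min_length: int = 20,
    scan: RetinalScan | np.ndarray | None = None,
) -> np.ndarray:
    """Segment the vessel tree from the TMAX response grid.

    Hysteresis thresholding of the [0, 1]-rescaled response, restricted
    to the circular field of view; when the source ``scan`` is given the
    mask is additionally confined to pixels darker than the local
    background, which trims the tensor response back to the vessel
    caliber. Components whose skeleton is shorter than ``min_length``
    pixels are removed.
    """
    if not (0 <= low < high <= 1):
        raise ValueError("thresholds must satisfy 0 <= low < high <= 1")
    response = np.asarray(response, float)
    gray = fov = None
    if scan is not None:
        gray = scan.gray() if isinstance(scan, RetinalScan) else np.asarray(scan, float)
        fov = field_of_view_mask(gray)
        if fov.any() and response[fov].max() > 0:
            # renormalize inside the field of view: the rim of the circular
            # aperture otherwise dominates the response scale
            response = response / response[fov].max()
    mask = filters.apply_hysteresis_threshold(response, low, high)
    if scan is not None:
        if fov.any():
            # vessels are darker than the smoothed local background
            background = uniform_filter(gray, size=31, mode="reflect")
            mask &= gray < background - 0.02
            mask &= fov
            # the tensor also responds to the outlines of bright blobs
            # (exudates, disc rim): near bright structure keep only pixels
            # decisively darker than their surround, so vessels crossing
            # the disc survive while blob outlines do not
            bright = gray > 1.25 * gray[fov].mean()
            if bright.any():
                near_bright = morphology.dilation(bright, morphology.disk(3))
                mask &= ~near_bright | (gray < background - 0.10)
    labels = measure.label(mask, connectivity=2)
    n = labels.max()
    if n == 0:
        return mask
    skeleton = morphology.skeletonize(mask)
    skel_len = ndimage.sum_labels(skeleton, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(skel_len >= min_length) + 1
    return np.isin(labels, keep)


def localize_optic_disc(
    scan: RetinalScan | np.ndarray, radius: int = 40, floor: float = 0.5
) -> tuple[int, int, int] | None:
    """Center of the brightest sliding disc, or None if nothing is bright.

    The regional mean over a disc footprint of the given radius is
    maximized; absence (max regional mean below ``floor``) is a value,
    not an error.
    """
    gray = scan.gray() if isinstance(scan, RetinalScan) else np.asarray(scan, float)
    if radius < 1:
        raise ValueError("disc radius must be positive")
    footprint = morphology.disk(radius).astype(float)
    footprint /= footprint.sum()
    regional = fftconvolve(gray, footprint, mode="same")
    peak = float(regional.max())
    if peak < floor:
        return None
    r, c = np.unravel_index(int(np.argmax(regional)), regional.shape)
    return int(r), int(c), int(radius)


def extract_exudates(
    scan: RetinalScan | np.ndarray,
    vessels: np.ndarray | None = None,
    disc: tuple[int, int, int] | None = None,
    t_bright: float = 1.3,
    min_area: int = 5,
    max_area: int = 2000,
    tophat_radius: int = 8,
    disc_dilation: float = 1.5,
    tophat_floor: float = 0.15,
) -> np.ndarray:
    """Segment hard exudates: small bright blobs away from disc and vessels.

    Candidates are pixels brighter than ``t_bright`` times the
    field-of-view mean whose top-hat response (small-scale brightness
    excess) also clears ``tophat_floor``, which rejects large smooth
    bright structure; candidate components intersecting the vessel mask or the
    disc region dilated by ``disc_dilation`` are removed, then components
    are filtered to [min_area, max_area].
    """
    gray = scan.gray() if isinstance(scan, RetinalScan) else np.asarray(scan, float)
    fov = field_of_view_mask(gray)
    if not fov.any():
        return np.zeros_like(gray, dtype=bool)
    enhanced = morphology.white_tophat(gray, morphology.disk(tophat_radius))
    fov_mean = gray[fov].mean()
    cand = fov & (gray > t_bright * fov_mean) & (enhanced > tophat_floor)
    disc_zone = np.zeros_like(cand)
    if disc is not None:
        r0, c0, rad = disc
        rr, cc = np.ogrid[: gray.shape[0], : gray.shape[1]]
        disc_zone = (rr - r0) ** 2 + (cc - c0) ** 2 <= (rad * disc_dilation) ** 2
    vessel_mask = np.asarray(vessels, bool) if vessels is not None else np.zeros_like(cand)
    labels = measure.label(cand, connectivity=2)
    out = np.zeros_like(cand)
    for region in measure.regionprops(labels):
        component = labels == region.label
        if not (min_area <= region.area <= max_area):
            continue
        if (component & disc_zone).any():
            continue
        # a candidate lying substantially on the vessel mask is a vessel
        # artifact; incidental contact does not disqualify it
        if (component & vessel_mask).sum() > 0.2 * region.area:
            continue
        out |= component
    # the exudate mask stays disjoint from vessels and the disc zone
    out &= ~vessel_mask
    out &= ~disc_zone
    return out


def fundus_findings(
    scan: RetinalScan,
    response: np.ndarray,
    low: float = 0.05,
    high: float = 0.20,
    min_length: int = 20,
    disc_radius: int = 40,
    disc_floor: float = 0.5,
    **exudate_kwargs,
) -> FindingMasks:
    """Convenience bundle: vessels, disc and exudates for one fundus scan."""
    vessels = extract_vessels(response, low, high, min_length, scan=scan)
    disc = localize_optic_disc(scan, radius=disc_radius, floor=disc_floor)
    exudates = extract_exudates(scan, vessels, disc, **exudate_kwargs)
    return FindingMasks(vessels=vessels, exudates=exudates, optic_disc=disc)
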