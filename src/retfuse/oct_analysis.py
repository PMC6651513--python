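"""OCT B-scan analysis: layer boundaries, fovea, retinal mask, fluid, CSME grade.

Boundary curves are traced on the Tyy structure-tensor response (retinal
layers are horizontally oriented) restricted to Canny edge pixels: each
curve starts at the topmost unclaimed edge pixel and is grown left and
right under a per-column jump limit, then median-smoothed. The ILM is
the topmost curve; the RPE is the deeper of the bottom two curves whose
underlying reflectivity is highest (the RPE complex is the brightest
band). Intraretinal fluid is segmented as hypo-reflective connected
components inside the ILM-RPE band, and the EDTRS rule grades edema as
clinically significant when fluid or exudates lie within 500 um lateral
distance of the fovea.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter, uniform_filter1d
from skimage import measure, morphology

from .scan_io import RetinalScan

GRADE_NONE = "none"
GRADE_CSME = "clinically_significant"
GRADE_NON_CSME = "non_significant"


class LayerExtractionError(RuntimeError):
    """Raised when a scan does not yield at least two boundary curves."""


@dataclass
class LayerBoundarySet:
    """Per-column depth curves for up to nine boundaries, top to bottom.

    Each curve is a float array of length ``cols`` with NaN where the
    boundary is undefined. ``ilm_index``/``rpe_index`` designate which
    curves are the inner limiting membrane and the retinal pigment
    epithelium.
    """

    boundaries: list[np.ndarray]
    ilm_index: int
    rpe_index: int

    def __post_init__(self) -> None:
        if len(self.boundaries) < 2:
            raise ValueError("a boundary set needs at least two curves")
        if len(self.boundaries) > 9:
            raise ValueError("at most nine boundary curves are supported")
        n = self.boundaries[0].size
        if any(b.size != n for b in self.boundaries):
            raise ValueError("boundary curves must share the column count")

    @property
    def ilm(self) -> np.ndarray:
        return self.boundaries[self.ilm_index]

    @property
    def rpe(self) -> np.ndarray:
        return self.boundaries[self.rpe_index]

    def ordering_violations(self, tol: float = 1.0) -> int:
        """Columns breaking the top-to-bottom ordering of consecutive curves.

        The ILM is the topmost curve and every boundary down to the RPE
        lies within the [ILM, RPE] bracket; a curve below the designated
        RPE (the bottom of the RPE complex) is allowed.
        """
        bad = 0
        for upper, lower in zip(self.boundaries, self.boundaries[1:]):
            ok = np.isfinite(upper) & np.isfinite(lower)
            bad += int(np.sum(upper[ok] > lower[ok] + tol))
        ilm, rpe = self.ilm, self.rpe
        for b in self.boundaries[self.ilm_index: self.rpe_index + 1]:
            ok = np.isfinite(b) & np.isfinite(ilm) & np.isfinite(rpe)
            bad += int(np.sum((b[ok] < ilm[ok] - tol) | (b[ok] > rpe[ok] + tol)))
        return bad


@dataclass
class FindingMasks:
    """Binary finding masks plus disc and fovea localizations."""

    fluid: np.ndarray | None = None
    vessels: np.ndarray | None = None
    exudates: np.ndarray | None = None
    optic_disc: tuple[int, int, int] | None = None  # (row, col, radius)
    fovea_col: int | None = None

    def lesion_columns(self) -> np.ndarray:
        cols: list[np.ndarray] = []
        for mask in (self.fluid, self.exudates):
            if mask is not None and mask.any():
                cols.append(np.nonzero(mask)[1])
        if not cols:
            return np.empty(0, dtype=int)
        return np.concatenate(cols)


def _trace_curve(
    avail: np.ndarray, response: np.ndarray, seed: tuple[int, int], jump_limit: int
) -> np.ndarray:
    """Grow one boundary curve from a seed edge pixel, left and right.

    At each neighboring column the candidate edge pixel within
    ``jump_limit`` rows of the previous position with the strongest
    response is taken; columns without a candidate keep the previous
    depth as the search anchor but stay undefined.
    """
    rows, cols = avail.shape
    curve = np.full(cols, np.nan)
    r0, c0 = seed
    curve[c0] = r0
    for step in (1, -1):
        prev = float(r0)
        rng = range(c0 + 1, cols) if step == 1 else range(c0 - 1, -1, -1)
        for c in rng:
            lo = max(int(round(prev)) - jump_limit, 0)
            hi = min(int(round(prev)) + jump_limit + 1, rows)
            cand = np.nonzero(avail[lo:hi, c])[0]
            if cand.size:
                r = lo + cand[np.argmax(response[lo + cand, c])]
                curve[c] = r
                prev = float(r)
    return curve


def _fill_and_smooth(curve: np.ndarray, window: int) -> np.ndarray:
    """Interpolate interior gaps and median-smooth over ``window`` columns."""
    defined = np.flatnonzero(np.isfinite(curve))
    filled = curve.copy()
    lo, hi = defined[0], defined[-1]
    span = np.arange(lo, hi + 1)
    filled[span] = np.interp(span, defined, curve[defined])
    filled[span] = median_filter(filled[span], size=min(window, span.size), mode="nearest")
    return filled


def extract_layers(
    response: np.ndarray,
    edges: np.ndarray,
    k: int = 9,
    jump_limit: int = 3,
    median_window: int = 15,
    brightness: np.ndarray | None = None,
    min_coverage: float = 0.5,
) -> LayerBoundarySet:
    """Trace up to ``k`` retinal layer boundaries from edge pixels.

    ``brightness`` (the denoised scan) is used to designate the RPE as
    the bottom curve with the brightest tissue beneath it; when absent
    the response grid is used instead.
    """
    if k < 2 or k > 9:
        raise ValueError("k must be between 2 and 9")
    response = np.asarray(response, float)
    edges = np.asarray(edges, bool)
    if response.shape != edges.shape:
        raise ValueError("response and edge grids must share one shape")
    rows, cols = edges.shape
    bright = response if brightness is None else np.asarray(brightness, float)
    # snap edge pixels to the response crest of their column: the tensor
    # response is a ridge centered on the boundary, and Canny marks its
    # flanks a few rows off
    cand = np.zeros_like(edges)
    snap = 5
    for r, c in zip(*np.nonzero(edges)):
        lo = max(r - snap, 0)
        window = response[lo: r + snap + 1, c]
        cand[lo + int(np.argmax(window)), c] = True
    # seeds and trace candidates are tracked separately: a failed (short)
    # trace burns its seeds but leaves its pixels available to later traces
    seed_avail = cand.copy()
    scored: list[tuple[float, np.ndarray]] = []
    attempts = 0
    while seed_avail.any() and attempts < 8 * k:
        attempts += 1
        rs, cs = np.nonzero(seed_avail)
        i = np.argmin(rs)  # topmost unclaimed edge pixel
        curve = _trace_curve(cand, response, (int(rs[i]), int(cs[i])), jump_limit)
        defined = np.isfinite(curve)
        coverage = float(defined.mean())
        # genuine layer boundaries are near-horizontal: a trace that jitters
        # from column to column is noise, not anatomy
        vals = curve[defined]
        roughness = float(np.abs(np.diff(vals)).mean()) if vals.size > 1 else 0.0
        accepted = coverage >= min_coverage and roughness <= 0.4
        for c in np.flatnonzero(defined):
            r = int(curve[c])
            seed_avail[max(r - 2, 0): r + 3, c] = False
            if accepted:
                cand[max(r - 2, 0): r + 3, c] = False
        if accepted:
            smoothed = _fill_and_smooth(curve, median_window)
            # drop ghost duplicates: residual crest pixels just outside a
            # claimed boundary can assemble a parallel copy of it
            dup = any(
                np.nanmedian(np.abs(smoothed - existing)) < 6.0 for _, existing in scored
            )
            if not dup:
                scored.append((coverage, smoothed))
    if len(scored) < 2:
        raise LayerExtractionError(
            f"only {len(scored)} boundary curve(s) could be assembled; scan unusable"
        )
    # keep the k best-supported curves, then order them top to bottom
    scored.sort(key=lambda t: -t[0])
    curves = [c for _, c in scored[:k]]
    curves.sort(key=lambda b: np.nanmean(b))
    # RPE: of the bottom two curves, the one with the brightest tissue beneath
    def under_brightness(b: np.ndarray) -> float:
        vals = []
        for c in np.flatnonzero(np.isfinite(b)):
            r = int(b[c])
            vals.append(bright[min(r + 1, rows - 1): min(r + 6, rows), c].mean())
        return float(np.mean(vals)) if vals else -np.inf

    if len(curves) == 2:
        rpe_index = 1  # nothing deeper to choose from
    else:
        bottom_two = [len(curves) - 2, len(curves) - 1]
        rpe_index = max(bottom_two, key=lambda i: under_brightness(curves[i]))
    return LayerBoundarySet(boundaries=curves, ilm_index=0, rpe_index=rpe_index)


def localize_fovea(ilm: np.ndarray, smooth_window: int = 15) -> int:
    """Column of the deepest (maximal-row) smoothed ILM point.

    Ties are broken toward the image-center column, deterministically.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be an odd positive integer")
    ilm = np.asarray(ilm, float)
    defined = np.isfinite(ilm)
    if defined.mean() < 0.5:
        raise ValueError("ILM must be defined on at least half of the columns")
    cols = ilm.size
    filled = ilm.copy()
    idx = np.flatnonzero(defined)
    filled[~defined] = np.interp(np.flatnonzero(~defined), idx, ilm[idx])
    smoothed = uniform_filter1d(filled, size=smooth_window, mode="nearest")
    peak = smoothed.max()
    # the foveal pit is locally flat: take the center of the deepest
    # plateau (within 1 px of the peak) containing the argmax
    near = smoothed >= peak - 1.0
    argmax = int(smoothed.argmax())
    lo = argmax
    while lo > 0 and near[lo - 1]:
        lo -= 1
    hi = argmax
    while hi < cols - 1 and near[hi + 1]:
        hi += 1
    candidates = np.arange(lo, hi + 1)
    center_of_plateau = candidates.mean()
    center = (cols - 1) / 2.0
    return int(min(candidates, key=lambda c: (abs(c - center_of_plateau), abs(c - center), c)))


def build_retinal_mask(layers: LayerBoundarySet, shape: tuple[int, int]) -> np.ndarray:
    """Binary mask of pixels strictly between the ILM and RPE per column."""
    rows, cols = shape
    if layers.ilm.size != cols:
        raise ValueError("boundary curves do not match the scan width")
    mask = np.zeros(shape, dtype=bool)
    rr = np.arange(rows)[:, None]
    ilm = layers.ilm[None, :]
    rpe = layers.rpe[None, :]
    with np.errstate(invalid="ignore"):
        mask = (rr > ilm) & (rr < rpe)
    return mask


def extract_fluid(
    denoised: RetinalScan | np.ndarray,
    mask: np.ndarray,
    t: float = 0.5,
    min_area: int = 30,
) -> np.ndarray:
    """Segment hypo-reflective intraretinal fluid inside the ILM-RPE band.

    The denoised scan is multiplied by the retinal mask; pixels darker
    than ``t`` times the in-band mean intensity survive a 3x3 opening and
    an area filter. The result is a subset of the band mask by
    construction.
    """
    img = denoised.gray() if isinstance(denoised, RetinalScan) else np.asarray(denoised, float)
    mask = np.asarray(mask, bool)
    if img.shape != mask.shape:
        raise ValueError("scan and mask must share one shape")
    if not mask.any():
        raise ValueError("retinal mask is empty")
    banded = img * mask
    mean_in = banded[mask].mean()
    cand = mask & (img < t * mean_in)
    cand = morphology.opening(cand, morphology.footprint_rectangle((3, 3)))
    cand &= mask
    labels = measure.label(cand, connectivity=2)
    out = np.zeros_like(mask)
    for region in measure.regionprops(labels):
        if region.area >= min_area:
            out[labels == region.label] = True
    return out


def grade_clinical_significance(
    masks: FindingMasks,
    fovea_col: int,
    um_per_pixel: float | None,
    distance_um: float = 500.0,
) -> str:
    """EDTRS grade: edema with lesions within ``distance_um`` of the fovea.

    Returns ``none`` when no fluid/exudate pixels exist, otherwise
    ``clinically_significant`` if any lesion pixel lies within the
    lateral distance of the fovea column, else ``non_significant``.
    """
    lesion_cols = masks.lesion_columns()
    if lesion_cols.size == 0:
        return GRADE_NONE
    if um_per_pixel is None or um_per_pixel <= 0:
        raise ValueError("lateral calibration (um/pixel) required to grade significance")
    dist = np.abs(lesion_cols - fovea_col) * um_per_pixel
    return GRADE_CSME if np.any(dist <= distance_um) else GRADE_NON_CSME
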