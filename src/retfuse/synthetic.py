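"""Seeded OCT and fundus phantoms with exact ground truth.

The OCT phantom emulates a foveal B-scan: stacked horizontal
reflectivity bands between an ILM and an RPE complex (the brightest
band), a parabolic foveal dip, multiplicative speckle, optional bright
scanner-annotation rows, and — for ME — hypo-reflective intraretinal
fluid blobs plus central thickening. The fundus phantom emulates a
posterior-pole photograph: a circular field of view, a bright optic
disc, a darker macula, a recursive branching dark vessel tree rooted at
the disc, and — for ME — bright hard-exudate blobs near the macula.
Every pixel of truth (boundaries, masks, centers) is recorded, and a
given seed reproduces a phantom bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage import draw, morphology

from .scan_io import DatasetManifest, ManifestRecord, RetinalScan, write_mask

DEFAULT_OCT_SHAPE = (496, 512)
DEFAULT_FUNDUS_SHAPE = (720, 576)
OCT_UM_PER_PIXEL = 11.6  # lateral calibration of the OCT phantom


@dataclass
class PhantomSpec:
    """Everything that determines a phantom; the seed fixes all randomness."""

    shape: tuple[int, int] = DEFAULT_OCT_SHAPE
    label: str = "healthy"
    n_layers: int = 9               # boundary curves in the OCT phantom (<= 9)
    speckle: float = 0.2            # multiplicative speckle level
    n_fluid_blobs: int | None = None    # ME only; None -> 1..4 drawn from the seed
    blob_radius: tuple[int, int] = (8, 22)
    vessel_depth: int = 5           # recursion depth of the fundus vessel tree
    n_exudates: int | None = None   # ME only; None -> 3..8 drawn from the seed
    annotation_rows: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.label not in ("healthy", "me"):
            raise ValueError("label must be healthy or me")
        if not (2 <= self.n_layers <= 9):
            raise ValueError("n_layers must be between 2 and 9")
        if self.speckle < 0:
            raise ValueError("speckle level must be nonnegative")
        if self.label == "healthy" and (self.n_fluid_blobs or self.n_exudates):
            raise ValueError("healthy phantoms cannot carry fluid or exudate blobs")
        if min(self.shape) < 64:
            raise ValueError("phantom shape too small")


@dataclass
class PhantomTruth:
    """Ground truth paired with a phantom scan."""

    label: str
    boundaries: list[np.ndarray] | None = None
    ilm_index: int | None = None
    rpe_index: int | None = None
    fluid: np.ndarray | None = None
    vessels: np.ndarray | None = None
    exudates: np.ndarray | None = None
    disc: tuple[int, int, int] | None = None
    fovea_col: int | None = None
    macula: tuple[int, int] | None = None


# ------------------------------------------------------------------ OCT

def generate_oct_phantom(spec: PhantomSpec) -> tuple[RetinalScan, PhantomTruth]:
    """Render a foveal OCT B-scan phantom and its truth."""
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    bg = 0.08
    img = np.full((rows, cols), bg)

    # boundary geometry: n_layers curves from the ILM down to the bottom of
    # the RPE complex, with a parabolic foveal dip of the inner boundaries
    top = int(rows * 0.33) + int(rng.integers(-10, 11))
    bottom = int(rows * 0.68) + int(rng.integers(-10, 11))
    fovea_col = cols // 2 + int(rng.integers(-20, 21))
    dip_half_width = cols * 0.12
    dip_depth = rows * 0.075
    thickening = rows * 0.035 if spec.label == "me" else 0.0

    n = spec.n_layers
    base = np.linspace(top, bottom, n)
    c = np.arange(cols)
    parabola = np.clip(1.0 - ((c - fovea_col) / dip_half_width) ** 2, 0.0, None)
    boundaries: list[np.ndarray] = []
    for i, b0 in enumerate(base):
        # the dip fades with depth; ME thickening pushes inner boundaries up
        frac = 1.0 - i / max(n - 1, 1)
        dip = dip_depth * parabola * frac
        lift = thickening * parabola * frac
        curve = b0 + dip - lift
        curve += rng.normal(0.0, 0.6)  # small per-boundary placement jitter
        boundaries.append(curve)

    # keep boundaries ordered with at least 2 px separation
    for i in range(1, n):
        boundaries[i] = np.maximum(boundaries[i], boundaries[i - 1] + 2.0)

    # band reflectivities: alternating contrast, the deepest band (the RPE
    # complex) is the brightest
    levels = [0.36, 0.24, 0.40, 0.26, 0.42, 0.28, 0.44]
    band_levels = levels[: n - 2] + [0.58]
    rr = np.arange(rows)[:, None]
    for i in range(n - 1):
        lo = boundaries[i][None, :]
        hi = boundaries[i + 1][None, :]
        img = np.where((rr >= lo) & (rr < hi), band_levels[i], img)

    ilm_index, rpe_index = 0, max(n - 2, 1)  # RPE = top of the bright complex

    fluid = np.zeros((rows, cols), dtype=bool)
    if spec.label == "me":
        n_blobs = (spec.n_fluid_blobs if spec.n_fluid_blobs is not None
                   else int(rng.integers(1, 5)))
        band_top = boundaries[min(1, n - 2)]
        band_bot = boundaries[rpe_index]
        placed = 0
        attempts = 0
        while placed < n_blobs and attempts < 200:
            attempts += 1
            a = int(rng.integers(*spec.blob_radius))          # semi-axis (cols)
            b = max(4, int(a * rng.uniform(0.4, 0.8)))        # semi-axis (rows)
            cc0 = int(rng.integers(int(cols * 0.2), int(cols * 0.8)))
            lo = float(band_top[cc0]) + b + 3
            hi = float(band_bot[cc0]) - b - 3
            if hi <= lo:
                continue
            rr0 = int(rng.uniform(lo, hi))
            rr_e, cc_e = draw.ellipse(rr0, cc0, b, a, shape=(rows, cols))
            inside = (rr_e > band_top[cc_e] + 1) & (rr_e < band_bot[cc_e] - 1)
            if inside.mean() < 0.999:
                continue
            cand = np.zeros_like(fluid)
            cand[rr_e, cc_e] = True
            if (cand & morphology.dilation(fluid, morphology.disk(3))).any():
                continue  # keep blobs as separate components
            fluid |= cand
            placed += 1
        img[fluid] = 0.05  # fluid is strongly hypo-reflective

    # multiplicative speckle
    if spec.speckle > 0:
        img = img * rng.uniform(1.0 - spec.speckle, 1.0 + spec.speckle, size=img.shape)

    # bright scanner annotation rows inside the first/last fifty rows
    if spec.annotation_rows:
        for r0 in (int(rng.integers(2, 20)), rows - int(rng.integers(5, 25))):
            img[r0:r0 + 3, int(cols * 0.05): int(cols * 0.45)] = 0.95

    img = np.clip(img, 0.0, 1.0)
    scan = RetinalScan(pixels=img, modality="oct", um_per_pixel=OCT_UM_PER_PIXEL,
                       source_id=f"oct-phantom-seed{spec.seed}")
    truth = PhantomTruth(
        label=spec.label,
        boundaries=boundaries,
        ilm_index=ilm_index,
        rpe_index=rpe_index,
        fluid=fluid,
        fovea_col=fovea_col,
    )
    return scan, truth


# ---------------------------------------------------------------- fundus

def _draw_vessel_tree(
    rng: np.random.Generator,
    shape: tuple[int, int],
    origin: tuple[float, float],
    depth: int,
    fov: np.ndarray,
) -> np.ndarray:
    """Recursive branching dark vessel tree rooted at the optic disc."""
    mask = np.zeros(shape, dtype=bool)

    def grow(r: float, c: float, angle: float, level: int) -> None:
        if level > depth:
            return
        width = max(1, 4 - level)
        n_segments = int(rng.integers(3, 6))
        for _ in range(n_segments):
            length = rng.uniform(25, 55)
            angle += rng.normal(0.0, 0.25)
            r2 = r + length * math.sin(angle)
            c2 = c + length * math.cos(angle)
            rr, cc = draw.line(int(round(r)), int(round(c)), int(round(r2)), int(round(c2)))
            ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
            seg = np.zeros(shape, dtype=bool)
            seg[rr[ok], cc[ok]] = True
            if width > 1:
                seg = morphology.dilation(seg, morphology.disk(width // 2))
            mask[seg & fov] = True
            r, c = r2, c2
            if not (0 <= r < shape[0] and 0 <= c < shape[1]):
                return
        for sign in (-1, 1):
            if rng.random() < 0.85:
                grow(r, c, angle + sign * rng.uniform(0.3, 0.7), level + 1)

    n_trunks = int(rng.integers(3, 5))
    for i in range(n_trunks):
        angle = rng.uniform(0, 2 * math.pi)
        grow(origin[0], origin[1], angle, 1)
    return mask


def generate_fundus_phantom(spec: PhantomSpec) -> tuple[RetinalScan, PhantomTruth]:
    """Render a posterior-pole fundus phantom (3-channel) and its truth."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape if spec.shape != DEFAULT_OCT_SHAPE else DEFAULT_FUNDUS_SHAPE
    rows, cols = shape
    rr, cc = np.mgrid[:rows, :cols]
    center = (rows / 2.0, cols / 2.0)
    fov_radius = min(rows, cols) / 2.0 - 8
    dist2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    fov = dist2 <= fov_radius ** 2

    green = np.zeros(shape)
    green[fov] = 0.45
    # gentle radial shading
    green[fov] *= 1.0 - 0.25 * (np.sqrt(dist2[fov]) / fov_radius) ** 2

    # optic disc: bright, smooth-edged, displaced toward one side
    disc_radius = int(min(rows, cols) * 0.07)
    side = -1 if rng.random() < 0.5 else 1
    disc_r = int(center[0] + rng.integers(-30, 31))
    disc_c = int(center[1] + side * cols * 0.28 + rng.integers(-15, 16))
    d2 = (rr - disc_r) ** 2 + (cc - disc_c) ** 2
    disc_profile = np.exp(-d2 / (2.0 * (disc_radius * 0.75) ** 2))
    green = np.where(fov, green + 0.40 * disc_profile, green)

    # macula: smooth dark region opposite the disc
    mac_r = int(center[0] + rng.integers(-20, 21))
    mac_c = int(center[1] - side * cols * 0.12 + rng.integers(-15, 16))
    m2 = (rr - mac_r) ** 2 + (cc - mac_c) ** 2
    green = np.where(fov, green - 0.18 * np.exp(-m2 / (2.0 * (disc_radius * 1.6) ** 2)), green)

    vessels = _draw_vessel_tree(rng, shape, (disc_r, disc_c), spec.vessel_depth, fov)
    green[vessels] -= 0.28

    exudates = np.zeros(shape, dtype=bool)
    if spec.label == "me":
        n_ex = spec.n_exudates if spec.n_exudates is not None else int(rng.integers(3, 9))
        max_dist = 3.0 * disc_radius  # within 1.5 disc-diameters of the macula
        forbidden = morphology.dilation(vessels, morphology.disk(4))
        placed = 0
        attempts = 0
        while placed < n_ex and attempts < 300:
            attempts += 1
            ang = rng.uniform(0, 2 * math.pi)
            rad = rng.uniform(disc_radius * 0.4, max_dist)
            er = int(mac_r + rad * math.sin(ang))
            ec = int(mac_c + rad * math.cos(ang))
            size = int(rng.integers(3, 8))
            if not (0 <= er < rows and 0 <= ec < cols) or not fov[er, ec]:
                continue
            if (er - disc_r) ** 2 + (ec - disc_c) ** 2 < (2.2 * disc_radius) ** 2:
                continue
            blob_rr, blob_cc = draw.disk((er, ec), size, shape=shape)
            cand = np.zeros(shape, dtype=bool)
            cand[blob_rr, blob_cc] = True
            cand &= fov
            if (cand & forbidden).any() or (cand & exudates).any():
                continue
            exudates |= cand
            placed += 1
        green[exudates] = 0.80

    if spec.speckle > 0:
        noise_level = min(spec.speckle * 0.1, 0.05)
        green = green + rng.normal(0.0, noise_level, size=shape) * fov

    green = np.clip(green, 0.0, 1.0)
    red = np.clip(green * 1.35, 0.0, 1.0) * fov
    blue = green * 0.35
    pixels = np.clip(np.stack([red, green, blue], axis=2), 0.0, 1.0)
    scan = RetinalScan(pixels=pixels, modality="fundus",
                       source_id=f"fundus-phantom-seed{spec.seed}")
    truth = PhantomTruth(
        label=spec.label,
        vessels=vessels,
        exudates=exudates,
        disc=(disc_r, disc_c, disc_radius),
        macula=(mac_r, mac_c),
        fovea_col=mac_c,
    )
    return scan, truth


# ---------------------------------------------------------------- cohort

@dataclass
class Subject:
    subject_id: str
    label: str
    split: str
    oct_scan: RetinalScan
    oct_truth: PhantomTruth
    fundus_scan: RetinalScan
    fundus_truth: PhantomTruth


def generate_cohort(
    n: int,
    prevalence: float = 0.5,
    seed: int = 0,
    outdir: str | Path | None = None,
    val_fraction: float = 0.25,
    speckle: float = 0.2,
) -> tuple[DatasetManifest, list[Subject]]:
    """Generate ``n`` subjects, each with one OCT and one fundus phantom.

    round(n * prevalence) subjects carry the ME label; both phantoms of a
    subject share its label. Subjects are assigned stratified
    train/validation splits. When ``outdir`` is given, scans, truth masks
    and the manifest CSV are written there.
    """
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    if not (0.0 <= prevalence <= 1.0):
        raise ValueError("prevalence must lie in [0, 1]")
    n_me = int(round(n * prevalence))
    labels = ["me"] * n_me + ["healthy"] * (n - n_me)
    ss = np.random.SeedSequence(seed)
    subject_seeds = ss.generate_state(2 * n) % (2 ** 31)

    # stratified split: last val_fraction of each class goes to validation
    split_of: dict[int, str] = {}
    for lab in ("me", "healthy"):
        idxs = [i for i, l in enumerate(labels) if l == lab]
        n_val = int(round(len(idxs) * val_fraction))
        for j, i in enumerate(idxs):
            split_of[i] = "validation" if j >= len(idxs) - n_val else "train"

    subjects: list[Subject] = []
    records: list[ManifestRecord] = []
    outdir_path = Path(outdir) if outdir is not None else None
    if outdir_path is not None:
        outdir_path.mkdir(parents=True, exist_ok=True)

    for i, label in enumerate(labels):
        sid = f"subject_{i:04d}"
        oct_spec = PhantomSpec(shape=DEFAULT_OCT_SHAPE, label=label,
                               speckle=speckle, seed=int(subject_seeds[2 * i]))
        fun_spec = PhantomSpec(shape=DEFAULT_FUNDUS_SHAPE, label=label,
                               speckle=speckle, seed=int(subject_seeds[2 * i + 1]))
        oct_scan, oct_truth = generate_oct_phantom(oct_spec)
        fun_scan, fun_truth = generate_fundus_phantom(fun_spec)
        split = split_of[i]
        subjects.append(Subject(sid, label, split, oct_scan, oct_truth, fun_scan, fun_truth))
        oct_name = f"{sid}_oct.png"
        fun_name = f"{sid}_fundus.png"
        records.append(ManifestRecord(oct_name, "oct", label, split))
        records.append(ManifestRecord(fun_name, "fundus", label, split))
        if outdir_path is not None:
            iio.imwrite(outdir_path / oct_name,
                        (oct_scan.pixels * 255).round().astype(np.uint8))
            iio.imwrite(outdir_path / fun_name,
                        (fun_scan.pixels * 255).round().astype(np.uint8))
            if oct_truth.fluid is not None:
                write_mask(outdir_path / f"{sid}_fluid_truth.png", oct_truth.fluid)
            if fun_truth.vessels is not None:
                write_mask(outdir_path / f"{sid}_vessels_truth.png", fun_truth.vessels)
            if fun_truth.exudates is not None:
                write_mask(outdir_path / f"{sid}_exudates_truth.png", fun_truth.exudates)

    manifest = DatasetManifest(records)
    if outdir_path is not None:
        manifest.to_csv(outdir_path / "manifest.csv")
    return manifest, subjects
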