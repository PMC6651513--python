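"""Layer extraction, fovea localization, retinal mask, fluid, EDTRS grading."""

import numpy as np
import pytest

from retfuse.oct_analysis import (
    GRADE_CSME,
    GRADE_NON_CSME,
    GRADE_NONE,
    FindingMasks,
    LayerBoundarySet,
    LayerExtractionError,
    build_retinal_mask,
    extract_fluid,
    extract_layers,
    grade_clinical_significance,
    localize_fovea,
)
from retfuse.pipeline import analyze_oct
from retfuse.synthetic import PhantomSpec, generate_oct_phantom
from retfuse.tensor import canny_edges, compute_structure_tensor, select_tensor
from retfuse.diagnosis import dice


def _flat_two_band(rows=400, cols=256, b1=100, b2=300):
    """Flat synthetic B-scan with boundaries at rows b1 and b2."""
    img = np.full((rows, cols), 0.05)
    img[b1:b2, :] = 0.45
    return img


def _layer_inputs(img):
    field = compute_structure_tensor(img, 1.0, 3.0)
    response = select_tensor(field, "oct_layers")
    edges = canny_edges(np.sqrt(response), 0.05, 0.15)
    return response, edges


class TestExtractLayers:
    def test_two_band_phantom_within_one_pixel(self):
        img = _flat_two_band()
        response, edges = _layer_inputs(img)
        layers = extract_layers(response, edges, k=2, brightness=img)
        assert len(layers.boundaries) == 2
        assert np.nanmax(np.abs(layers.boundaries[0] - 100)) <= 1.0
        assert np.nanmax(np.abs(layers.boundaries[1] - 300)) <= 1.0

    def test_nine_band_phantom_mean_error_within_two_pixels(self):
        scan, truth = generate_oct_phantom(PhantomSpec(label="healthy", seed=7))
        findings = analyze_oct(scan)
        assert len(findings.layers.boundaries) == 9
        maes = [
            min(np.nanmean(np.abs(b - tb)) for b in findings.layers.boundaries)
            for tb in truth.boundaries
        ]
        assert np.mean(maes) <= 2.0
        assert max(maes) <= 4.0

    def test_pure_noise_raises_extraction_error(self):
        rng = np.random.default_rng(0)
        img = rng.random((200, 128))
        response, edges = _layer_inputs(img)
        with pytest.raises(LayerExtractionError):
            extract_layers(response, edges)

    def test_boundary_ordering_invariant(self, me_oct_phantom):
        scan, _ = me_oct_phantom
        layers = analyze_oct(scan).layers
        assert layers.ordering_violations(tol=1.0) == 0
        mean_rows = [np.nanmean(b) for b in layers.boundaries]
        assert mean_rows == sorted(mean_rows)


class TestLocalizeFovea:
    def test_parabolic_ilm_vertex_found(self):
        c = np.arange(512)
        ilm = 150 + 40 * np.clip(1 - ((c - 256) / 60.0) ** 2, 0, None)
        assert localize_fovea(ilm, 15) == 256

    def test_flat_ilm_center_tie_break(self):
        assert localize_fovea(np.full(512, 200.0), 15) in (255, 256)
        # deterministic
        assert localize_fovea(np.full(512, 200.0), 15) == localize_fovea(
            np.full(512, 200.0), 15
        )

    def test_noisy_parabola_within_two_columns(self):
        rng = np.random.default_rng(3)
        c = np.arange(512)
        ilm = 150 + 40 * np.clip(1 - ((c - 300) / 60.0) ** 2, 0, None)
        ilm = ilm + rng.normal(0, 2.0, size=512)
        assert abs(localize_fovea(ilm, 15) - 300) <= 2

    def test_undefined_ilm_rejected(self):
        ilm = np.full(100, np.nan)
        ilm[:10] = 50.0
        with pytest.raises(ValueError):
            localize_fovea(ilm, 15)


class TestBuildRetinalMask:
    def _layers(self, cols, ilm_row, rpe_row):
        b = [np.full(cols, float(ilm_row)), np.full(cols, float(rpe_row))]
        return LayerBoundarySet(b, ilm_index=0, rpe_index=1)

    def test_flat_band_has_exact_count(self):
        mask = build_retinal_mask(self._layers(64, 100, 300), (400, 64))
        assert np.all(mask.sum(axis=0) == 199)  # rows 101..299 inclusive

    def test_degenerate_band_is_empty(self):
        mask = build_retinal_mask(self._layers(64, 150, 150), (400, 64))
        assert not mask.any()

    def test_mask_strictly_inside_curves(self):
        mask = build_retinal_mask(self._layers(32, 10, 20), (40, 32))
        rows = np.nonzero(mask.any(axis=1))[0]
        assert rows.min() == 11 and rows.max() == 19


class TestExtractFluid:
    def test_healthy_phantom_has_empty_fluid(self, healthy_oct_phantom):
        scan, _ = healthy_oct_phantom
        findings = analyze_oct(scan)
        assert not findings.fluid.any()

    def test_me_phantom_two_blobs_recovered(self, me_oct_phantom):
        from scipy.ndimage import label

        scan, truth = me_oct_phantom
        findings = analyze_oct(scan)
        assert label(findings.fluid)[1] == 2
        assert dice(findings.fluid, truth.fluid) >= 0.80

    def test_fluid_subset_of_band(self, me_oct_phantom):
        scan, _ = me_oct_phantom
        findings = analyze_oct(scan)
        assert not (findings.fluid & ~findings.band_mask).any()

    def test_blob_outside_band_not_detected(self):
        img = _flat_two_band()
        img[320:340, 100:140] = 0.0  # dark blob below the band
        response, edges = _layer_inputs(img)
        layers = extract_layers(response, edges, k=2, brightness=img)
        mask = build_retinal_mask(layers, img.shape)
        fluid = extract_fluid(img, mask, t=0.5, min_area=30)
        assert not fluid[320:340, 100:140].any()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_fluid(np.zeros((10, 10)), np.zeros((10, 10), bool))


class TestGradeClinicalSignificance:
    um = 11.6

    def _masks_with_lesion_at(self, col):
        fluid = np.zeros((100, 600), bool)
        fluid[50, col] = True
        return FindingMasks(fluid=fluid)

    def test_lesion_within_500um_is_significant(self):
        # 200 um away at 11.6 um/px is ~17 columns
        masks = self._masks_with_lesion_at(300 + 17)
        assert grade_clinical_significance(masks, 300, self.um) == GRADE_CSME

    def test_lesion_beyond_500um_is_non_significant(self):
        # 600 um away is ~52 columns
        masks = self._masks_with_lesion_at(300 + 52)
        assert grade_clinical_significance(masks, 300, self.um) == GRADE_NON_CSME

    def test_empty_masks_grade_none(self):
        masks = FindingMasks(fluid=np.zeros((10, 10), bool))
        assert grade_clinical_significance(masks, 5, self.um) == GRADE_NONE

    def test_missing_calibration_with_lesions_rejected(self):
        with pytest.raises(ValueError):
            grade_clinical_significance(self._masks_with_lesion_at(10), 5, None)
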