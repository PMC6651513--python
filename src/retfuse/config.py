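"""Single configuration object governing every tunable threshold in the pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All pipeline thresholds in one place, loadable from YAML.

    Intensities are normalized to [0, 1] on load, so every threshold here
    is scale-free. Distances are in pixels unless the name says otherwise.
    """

    # preprocessing
    annotation_rows: int = 50          # rows blanked at top and bottom of a B-scan
    gradient_thresh: float = 0.65       # "sharp transition" column-gradient threshold
    wiener_wh: int = 5                 # Wiener window width (odd)
    wiener_wv: int = 5                 # Wiener window height (odd)
    noise_floor: float | None = None   # a^2; None -> mean of local variances

    # structure tensor
    sigma_d: float = 1.0               # Gaussian derivative scale
    sigma_w: float = 3.0               # Gaussian window scale g(x, y)
    canny_low: float = 0.05
    canny_high: float = 0.15

    # OCT layer / fluid extraction
    max_layers: int = 9
    jump_limit: int = 3                # max inter-column jump of a boundary curve
    median_window: int = 15            # boundary median-smoothing window (columns)
    fovea_smooth_window: int = 15
    fluid_thresh: float = 0.5          # relative to mean intensity inside the ILM-RPE band
    fluid_min_area: int = 30

    # fundus extraction
    vessel_low: float = 0.05
    vessel_high: float = 0.20
    vessel_min_length: int = 20        # skeleton length (pixels)
    disc_radius: int = 40
    disc_floor: float = 0.5            # minimum regional mean for a disc to count
    disc_dilation: float = 1.5         # exclusion zone = detected radius x this
    tophat_radius: int = 8
    tophat_floor: float = 0.15
    exudate_thresh: float = 1.3        # relative to field-of-view mean
    exudate_min_area: int = 5
    exudate_max_area: int = 2000

    # EDTRS clinical significance
    csme_distance_um: float = 500.0    # lesion-to-fovea lateral distance
    um_per_pixel: float = 11.6         # lateral calibration default

    # CNN / training
    cnn_input_size: int = 227          # Table-geometry default; training uses smaller
    sgd_lr: float = 0.001
    sgd_momentum: float = 0.9
    batch_size: int = 16

    # classifiers
    svm_c: float = 1.0
    svm_gamma: float = 1.0 / 16.0
    mlp_kernel_scale: float = 1.0 / 16.0
    mlp_kernel_offset: float = -1.0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
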