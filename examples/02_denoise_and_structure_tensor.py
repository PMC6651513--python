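"""Preprocess an OCT B-scan and inspect the structure-tensor channels.

Shows the three preprocessing steps (annotation-row stripping,
degraded-margin repair, adaptive Wiener denoising) and how the tensor's
energy splits between the Txx (vertical structure) and Tyy (horizontal
structure) channels. On a B-scan the retinal layers are horizontal, so
Tyy carries the layer information and is the most coherent channel.
"""

import numpy as np

from retfuse import (
    DenoiseParams,
    PhantomSpec,
    coherence,
    compute_structure_tensor,
    generate_oct_phantom,
    repair_degraded_regions,
    strip_annotation_rows,
    wiener_denoise,
)

scan, _ = generate_oct_phantom(PhantomSpec(label="healthy", seed=11))
stripped = strip_annotation_rows(scan, 50)
repaired = repair_degraded_regions(stripped)
denoised = wiener_denoise(repaired, DenoiseParams(wh=5, wv=5))
print(f"variance before Wiener filter {repaired.pixels.var():.5f}")
print(f"variance after Wiener filter  {denoised.pixels.var():.5f}  (speckle suppressed)")

field = compute_structure_tensor(denoised, sigma_d=1.0, sigma_w=3.0)
print(f"sum Txx = {field.txx.sum():.2f}, sum Tyy = {field.tyy.sum():.2f}")
summary = coherence(field)
print(f"most coherent channel: {summary.most_coherent_channel()}  "
      f"(scores: { {k: round(v, 5) for k, v in summary.channel_scores.items()} })")
# Tyy dominates because the layer boundaries are horizontal edges: their
# intensity gradient points vertically (along y).
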