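"""Generate one OCT and one fundus phantom with ground truth and print what they contain.

The OCT phantom is a foveal B-scan: nine stacked reflectivity bands with
a foveal dip, multiplicative speckle and (for the ME case) dark
intraretinal fluid blobs. The fundus phantom is a posterior-pole
photograph: circular field of view, bright optic disc, darker macula,
branching vessel tree and (ME) bright exudates near the macula.
"""

from retfuse import PhantomSpec, generate_fundus_phantom, generate_oct_phantom
from retfuse.synthetic import DEFAULT_FUNDUS_SHAPE

oct_scan, oct_truth = generate_oct_phantom(PhantomSpec(label="me", seed=5, n_fluid_blobs=2))
print(f"OCT phantom: {oct_scan.rows}x{oct_scan.cols}, label={oct_truth.label}")
print(f"  {len(oct_truth.boundaries)} layer boundaries; ILM mean row "
      f"{oct_truth.boundaries[oct_truth.ilm_index].mean():.1f}, "
      f"RPE mean row {oct_truth.boundaries[oct_truth.rpe_index].mean():.1f}")
print(f"  fluid pixels: {int(oct_truth.fluid.sum())}, true fovea column: {oct_truth.fovea_col}")

fun_scan, fun_truth = generate_fundus_phantom(
    PhantomSpec(shape=DEFAULT_FUNDUS_SHAPE, label="me", seed=13)
)
print(f"fundus phantom: {fun_scan.rows}x{fun_scan.cols}x3, label={fun_truth.label}")
print(f"  vessel pixels: {int(fun_truth.vessels.sum())}, "
      f"exudate pixels: {int(fun_truth.exudates.sum())}, "
      f"disc at (row, col, r) = {fun_truth.disc}")
# The truth masks are the reference every extraction stage is scored against.
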