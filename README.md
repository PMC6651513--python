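# retfuse

Automated grading of **macular edema (ME)** from a *pair* of retinal
scans — one OCT B-scan and one fundus photograph — for researchers who
want a fully reproducible, dependency-light reimplementation of a fused
two-modality grading pipeline that they can run, test and extend on
synthetic data without any clinical image downloads.

ME is the accumulation of fluid in the macula; it is best seen as
hypo-reflective intraretinal fluid on OCT and as hard exudates on fundus
photographs. `retfuse` fuses both views:

1. **Modality recognition** — a small CNN tags each input as `oct` or
   `fundus`.
2. **Preprocessing** — scanner annotation rows are blanked (first/last
   50 rows of a B-scan), degraded margins are repaired column-by-column,
   and speckle is suppressed with a pixel-wise adaptive Wiener filter
   `D = m + (s² − a²)⁺/s² (O − m)` over a local window (`m`, `s²` local
   mean/variance; `a²` the noise floor, estimated as the mean of all
   local variances).
3. **Finding extraction** — the second-moment structure tensor
   `sT = [[Txx, Txy], [Txy, Tyy]]` of Gaussian-derivative responses is
   computed per pixel; its eigenvalues give the coherence
   `c = ((λ₁−λ₂)/(λ₁+λ₂))²`. On OCT the `Tyy` channel (horizontal
   layering) drives extraction of up to nine retinal layer boundaries,
   the fovea (deepest ILM point), the ILM–RPE retinal mask and the fluid
   mask; on fundus the `TMAX = max(Txx, Tyy)` fusion drives vessel
   segmentation, optic-disc localization and hard-exudate extraction.
   ME is graded *clinically significant* (EDTRS) when lesions lie within
   500 µm lateral distance of the fovea.
4. **CNN features** — a 14-layer CNN (three 9×9 convolution blocks with
   batch normalization, two max pools, 50 % dropout, an 8-unit fully
   connected output) is trained on the finding-overlaid scans; eight OCT
   features and eight fundus features are concatenated into a 16-D
   descriptor.
5. **Hybrid diagnosis** — an ANN (16–12–9–2, sigmoid hidden layers), an
   SVM (RBF or MLP kernel) and a Gaussian naive Bayes each vote; the
   final label is the majority. Performance is reported as sensitivity,
   specificity, PPV, NPV and diagnostic accuracy from the confusion
   counts, plus dice overlap for each finding mask.

Everything runs on seeded synthetic phantoms produced by
`retfuse.synthetic`: OCT B-scans with stacked reflectivity bands, a
foveal dip, multiplicative speckle and fluid blobs; fundus images with a
circular field of view, a branching vessel tree, a bright disc, a darker
macula and exudates — each with exact ground-truth masks.

## Worked example

```bash
python examples/03_oct_findings.py
```

prints (seed 5, an ME phantom with two fluid blobs):

```
boundaries extracted: 9 (ILM index 0, RPE index 7)
boundary MAE per true curve: [0.46, 0.44, 0.43, 0.39, 0.39, 0.45, 0.56, 0.44, 0.29] px
fovea column: 236 (truth 236)
fluid dice vs truth: 1.000
EDTRS grade: clinically_significant
```

All nine layer boundaries are recovered to sub-pixel accuracy, the
fovea lands on the true dip column, the fluid mask matches the phantom
truth, and — because fluid encroaches within 500 µm of the fovea — the
edema is graded clinically significant. The other scripts in
`examples/` walk through phantom generation, denoising + tensor
channels, fundus findings, and full training + diagnosis.

A thin CLI mirrors the stages (`retfuse synth`, `preprocess`, `tensor`,
`oct-extract`, `fundus-extract`, `train-cnn`, `diagnose`, `evaluate`);
run `retfuse --help`. Every threshold lives in one YAML config
(`retfuse config-template`).

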