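"""End-to-end orchestration of the five-stage grading pipeline.

Stage order per scan pair: recognize the modality of each input (and
verify the pair is one OCT + one fundus), preprocess, extract the
clinically significant findings, overlay them on the scan, extract
eight CNN features per modality, fuse into the 16-D vector, and let the
ANN/SVM/NB ensemble vote. The report carries the masks, the feature
vector, the per-classifier votes, the final label, and the EDTRS
clinical-significance grade when lateral calibration is available.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np

from .config import PipelineConfig
from .diagnosis import (
    ANNModel,
    ConfusionCounts,
    FeatureScaler,
    GaussianNBModel,
    classification_metrics,
    dice,
    predict_ensemble,
    train_ann,
    train_nb,
    train_svm,
)
from .features import (
    CNNConfig,
    FeatureCNN,
    TrainingLog,
    build_feature_cnn,
    fit_cnn,
    fuse_features,
    overlay_findings,
    prepare_input,
    recognize_modality,
)
from .fundus_analysis import extract_exudates, extract_vessels, localize_optic_disc
from .oct_analysis import (
    FindingMasks,
    LayerBoundarySet,
    build_retinal_mask,
    extract_fluid,
    extract_layers,
    grade_clinical_significance,
    localize_fovea,
)
from .preprocess import DenoiseParams, repair_degraded_regions, strip_annotation_rows, wiener_denoise
from .scan_io import RetinalScan
from .synthetic import Subject
from .tensor import canny_edges, compute_structure_tensor, select_tensor

logger = logging.getLogger(__name__)


# ------------------------------------------------------------ finding stages

@dataclass
class OCTFindings:
    denoised: RetinalScan
    response: np.ndarray
    edges: np.ndarray
    layers: LayerBoundarySet
    band_mask: np.ndarray
    fluid: np.ndarray
    fovea_col: int


@dataclass
class FundusFindings:
    denoised: RetinalScan
    response: np.ndarray
    vessels: np.ndarray
    disc: tuple[int, int, int] | None
    exudates: np.ndarray


def analyze_oct(scan: RetinalScan, config: PipelineConfig | None = None) -> OCTFindings:
    """Preprocess one OCT B-scan and extract layers, fovea and fluid."""
    config = config or PipelineConfig()
    stripped = strip_annotation_rows(scan, config.annotation_rows)
    repaired = repair_degraded_regions(stripped, config.gradient_thresh)
    denoised = wiener_denoise(
        repaired,
        DenoiseParams(config.wiener_wh, config.wiener_wv, config.noise_floor),
    )
    field = compute_structure_tensor(denoised, config.sigma_d, config.sigma_w)
    response = select_tensor(field, "oct_layers")
    # gamma compression evens out boundary contrasts (the vitreous-choroid
    # steps dominate the inner-layer steps by an order of magnitude)
    edges = canny_edges(np.sqrt(response), config.canny_low, config.canny_high)
    layers = extract_layers(
        response,
        edges,
        k=config.max_layers,
        jump_limit=config.jump_limit,
        median_window=config.median_window,
        brightness=denoised.gray(),
    )
    fovea_col = localize_fovea(layers.ilm, config.fovea_smooth_window)
    band = build_retinal_mask(layers, denoised.gray().shape)
    fluid = extract_fluid(denoised, band, config.fluid_thresh, config.fluid_min_area)
    return OCTFindings(denoised, response, edges, layers, band, fluid, fovea_col)


def analyze_fundus(scan: RetinalScan, config: PipelineConfig | None = None) -> FundusFindings:
    """Denoise one fundus scan and extract vessels, disc and exudates."""
    config = config or PipelineConfig()
    gray_scan = RetinalScan(scan.gray(), modality="fundus")
    gray_denoised = wiener_denoise(
        gray_scan, DenoiseParams(config.wiener_wh, config.wiener_wv, config.noise_floor)
    )
    field = compute_structure_tensor(gray_denoised, config.sigma_d, config.sigma_w)
    response = select_tensor(field, "fundus_vessels")
    vessels = extract_vessels(
        response, config.vessel_low, config.vessel_high, config.vessel_min_length,
        scan=gray_denoised,
    )
    disc = localize_optic_disc(gray_denoised, config.disc_radius, config.disc_floor)
    exudates = extract_exudates(
        gray_denoised, vessels, disc,
        t_bright=config.exudate_thresh,
        min_area=config.exudate_min_area,
        max_area=config.exudate_max_area,
        tophat_radius=config.tophat_radius,
        disc_dilation=config.disc_dilation,
        tophat_floor=config.tophat_floor,
    )
    return FundusFindings(gray_denoised, response, vessels, disc, exudates)


# ---------------------------------------------------------------- the bundle

@dataclass
class ModelBundle:
    """Everything trained: modality CNN, feature CNN, the three classifiers."""

    modality_cnn: FeatureCNN
    feature_cnn: FeatureCNN
    ann: ANNModel
    svm: object
    nb: GaussianNBModel
    scaler: FeatureScaler

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, net in (("modality_cnn", self.modality_cnn), ("feature_cnn", self.feature_cnn)):
            np.savez(directory / f"{name}.npz", **net.net.state_dict(),
                     zero_center=np.float32(net.net.layers[0].mean))
            meta = {
                "input_size": net.config.input_size,
                "n_classes": net.n_classes,
                "class_names": net.class_names,
            }
            (directory / f"{name}.json").write_text(json.dumps(meta))
        np.savez(directory / "ann.npz", **self.ann.net.state_dict())
        joblib.dump(self.svm, directory / "svm.joblib")
        np.savez(directory / "nb.npz", priors=self.nb.priors, means=self.nb.means,
                 variances=self.nb.variances)
        np.savez(directory / "scaler.npz", mean=self.scaler.mean, std=self.scaler.std)

    @classmethod
    def load(cls, directory: str | Path) -> "ModelBundle":
        directory = Path(directory)
        nets = {}
        for name in ("modality_cnn", "feature_cnn"):
            meta = json.loads((directory / f"{name}.json").read_text())
            net = build_feature_cnn(CNNConfig(input_size=meta["input_size"]),
                                    n_classes=meta["n_classes"])
            state = dict(np.load(directory / f"{name}.npz"))
            net.net.layers[0].mean = np.float32(state.pop("zero_center"))
            net.net.load_state_dict(state)
            net.class_names = meta["class_names"]
            net.trained = True
            nets[name] = net
        ann_state = dict(np.load(directory / "ann.npz"))
        ann = ANNModel(n_inputs=ann_state["0.W"].shape[0])
        ann.net.load_state_dict(ann_state)
        nb_state = np.load(directory / "nb.npz")
        nb = GaussianNBModel(nb_state["priors"], nb_state["means"], nb_state["variances"])
        sc = np.load(directory / "scaler.npz")
        return cls(
            modality_cnn=nets["modality_cnn"],
            feature_cnn=nets["feature_cnn"],
            ann=ann,
            svm=joblib.load(directory / "svm.joblib"),
            nb=nb,
            scaler=FeatureScaler(mean=sc["mean"], std=sc["std"]),
        )


def _subject_overlays(
    subject: Subject, config: PipelineConfig, input_size: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Overlaid OCT and fundus images for one subject (findings burned in).

    With ``input_size`` the overlays are returned already resized to the
    CNN input, which keeps cohort-scale training memory small.
    """
    oct_f = analyze_oct(subject.oct_scan, config)
    fun_f = analyze_fundus(subject.fundus_scan, config)
    oct_overlay = overlay_findings(
        oct_f.denoised, FindingMasks(fluid=oct_f.fluid), layers=oct_f.layers
    )
    fun_overlay = overlay_findings(
        subject.fundus_scan,
        FindingMasks(vessels=fun_f.vessels, exudates=fun_f.exudates, optic_disc=fun_f.disc),
    )
    if input_size is not None:
        return prepare_input(oct_overlay, input_size), prepare_input(fun_overlay, input_size)
    return oct_overlay, fun_overlay


def train_models(
    subjects: list[Subject],
    config: PipelineConfig | None = None,
    seed: int = 0,
    input_size: int = 64,
    feature_epochs: int = 30,
    modality_epochs: int = 4,
) -> tuple[ModelBundle, dict[str, TrainingLog]]:
    """Train the full bundle on a synthetic cohort's training split.

    The modality CNN learns oct-vs-fundus on the raw scans; the feature
    CNN learns healthy-vs-ME on the finding-overlaid scans of both
    modalities; the ensemble is trained on the fused, standardized 16-D
    vectors. Everything is seeded.
    """
    config = config or PipelineConfig()
    train_subjects = [s for s in subjects if s.split == "train"]
    val_subjects = [s for s in subjects if s.split == "validation"]
    if not train_subjects:
        raise ValueError("no training subjects")
    labels = {s.label for s in train_subjects}
    if labels != {"healthy", "me"}:
        raise ValueError("training split must contain both classes")

    logger.info("extracting findings for %d training subjects", len(train_subjects))
    overlays: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for s in train_subjects + val_subjects:
        overlays[s.subject_id] = _subject_overlays(s, config, input_size=input_size)

    def stack(subs: list[Subject], kind: str) -> tuple[np.ndarray, np.ndarray]:
        xs, ys = [], []
        for s in subs:
            oct_ov, fun_ov = overlays[s.subject_id]
            xs.append(oct_ov if kind == "oct" else fun_ov)
            ys.append(1 if s.label == "me" else 0)
        return np.stack(xs), np.asarray(ys, int)

    # modality CNN: raw scans, oct-vs-fundus
    mod_x = np.stack(
        [prepare_input(s.oct_scan, input_size) for s in train_subjects]
        + [prepare_input(s.fundus_scan, input_size) for s in train_subjects]
    )
    mod_y = np.concatenate([np.zeros(len(train_subjects), int), np.ones(len(train_subjects), int)])
    modality_cnn = build_feature_cnn(CNNConfig(input_size=input_size), seed=seed)
    mod_log = fit_cnn(
        modality_cnn, mod_x, mod_y, ["oct", "fundus"],
        epochs=modality_epochs, lr=config.sgd_lr, momentum=config.sgd_momentum,
        batch_size=config.batch_size, seed=seed,
    )

    # feature CNN: overlaid scans of both modalities, healthy-vs-ME
    xo, yo = stack(train_subjects, "oct")
    xf, yf = stack(train_subjects, "fundus")
    feat_x = np.concatenate([xo, xf])
    feat_y = np.concatenate([yo, yf])
    xv = yv = None
    if val_subjects:
        xvo, yvo = stack(val_subjects, "oct")
        xvf, yvf = stack(val_subjects, "fundus")
        xv, yv = np.concatenate([xvo, xvf]), np.concatenate([yvo, yvf])
    feature_cnn = build_feature_cnn(CNNConfig(input_size=input_size), seed=seed + 1)
    feat_log = fit_cnn(
        feature_cnn, feat_x, feat_y, ["healthy", "me"],
        epochs=feature_epochs, lr=config.sgd_lr, momentum=config.sgd_momentum,
        batch_size=config.batch_size, seed=seed + 1, x_val=xv, y_val=yv,
    )

    # fused 16-D vectors for the ensemble
    def fused(subs: list[Subject]) -> tuple[np.ndarray, np.ndarray]:
        vecs, ys = [], []
        for s in subs:
            oct_ov, fun_ov = overlays[s.subject_id]
            f_oct = feature_cnn.features(oct_ov)[0]
            f_fun = feature_cnn.features(fun_ov)[0]
            vecs.append(np.concatenate([f_oct, f_fun]))
            ys.append(1 if s.label == "me" else 0)
        return np.stack(vecs), np.asarray(ys, int)

    x_train, y_train = fused(train_subjects)
    scaler = FeatureScaler.fit(x_train)
    xs = scaler.transform(x_train)
    ann = train_ann(xs, y_train, seed=seed)
    svm = train_svm(xs, y_train, kernel="rbf", c=config.svm_c, gamma=config.svm_gamma, seed=seed)
    nb = train_nb(xs, y_train)

    bundle = ModelBundle(modality_cnn, feature_cnn, ann, svm, nb, scaler)
    return bundle, {"modality": mod_log, "features": feat_log}


# -------------------------------------------------------------- end to end

def run_end_to_end(
    scan_a: RetinalScan,
    scan_b: RetinalScan | None,
    bundle: ModelBundle,
    config: PipelineConfig | None = None,
    expected_modalities: tuple[str, ...] | None = None,
    allow_single: bool = False,
) -> dict:
    """Grade one subject from a pair of scans (one OCT + one fundus).

    ``expected_modalities`` lets a manifest override recognition (the
    manifest's modality tags are ground truth; a disagreement is logged).
    With ``allow_single`` one scan may be omitted: the missing modality's
    eight features are zero-filled and the report is marked degraded —
    the method's point is fusing both views, so this is explicit and
    logged, never silent. Returns a report dict with votes, final label,
    the feature vector, the finding masks and the CSME grade.
    """
    config = config or PipelineConfig()
    scans = [s for s in (scan_a, scan_b) if s is not None]
    recognized = []
    for i, scan in enumerate(scans):
        modality, prob = recognize_modality(bundle.modality_cnn, scan)
        if expected_modalities is not None:
            if modality != expected_modalities[i]:
                logger.warning(
                    "recognized %s (p=%.2f) but manifest says %s; trusting the manifest",
                    modality, prob, expected_modalities[i],
                )
            modality = expected_modalities[i]
            scan.modality = modality
        recognized.append((modality, prob))
    modalities = [m for m, _ in recognized]
    degraded = len(scans) == 1
    if degraded and not allow_single:
        raise ValueError("expected one OCT and one fundus scan; "
                         "pass allow_single=True for degraded single-modality grading")
    if not degraded and sorted(modalities) != ["fundus", "oct"]:
        raise ValueError("expected one OCT and one fundus scan, got " + " + ".join(modalities))
    if degraded:
        logger.warning("single-%s grading: the other modality's features are zero-filled",
                       modalities[0])
    oct_scan = scans[modalities.index("oct")] if "oct" in modalities else None
    fundus_scan = scans[modalities.index("fundus")] if "fundus" in modalities else None

    size = bundle.feature_cnn.config.input_size
    oct_f = fun_f = None
    f_oct = np.zeros(8)
    f_fun = np.zeros(8)
    if oct_scan is not None:
        oct_f = analyze_oct(oct_scan, config)
        oct_overlay = overlay_findings(oct_f.denoised, FindingMasks(fluid=oct_f.fluid),
                                       layers=oct_f.layers)
        f_oct = bundle.feature_cnn.features(prepare_input(oct_overlay, size))[0]
    if fundus_scan is not None:
        fun_f = analyze_fundus(fundus_scan, config)
        fun_overlay = overlay_findings(
            fundus_scan,
            FindingMasks(vessels=fun_f.vessels, exudates=fun_f.exudates, optic_disc=fun_f.disc),
        )
        f_fun = bundle.feature_cnn.features(prepare_input(fun_overlay, size))[0]
    fv = fuse_features(f_oct, f_fun)
    diagnosis = predict_ensemble(bundle.ann, bundle.svm, bundle.nb, fv, scaler=bundle.scaler)

    csme = None
    if oct_scan is not None:
        um = oct_scan.um_per_pixel or config.um_per_pixel
        if um is not None:
            csme = grade_clinical_significance(
                FindingMasks(fluid=oct_f.fluid), oct_f.fovea_col, um, config.csme_distance_um
            )
            diagnosis.csme_grade = csme

    return {
        "votes": diagnosis.votes,
        "final": diagnosis.final,
        "posterior": diagnosis.posterior,
        "csme_grade": csme,
        "feature_vector": fv.values.tolist(),
        "fovea_col": oct_f.fovea_col if oct_f is not None else None,
        "recognized": recognized,
        "degraded": degraded,
        "oct_findings": oct_f,
        "fundus_findings": fun_f,
    }


def evaluate_cohort(
    subjects: list[Subject],
    bundle: ModelBundle,
    config: PipelineConfig | None = None,
    split: str = "validation",
) -> dict:
    """Diagnose every subject of a split and aggregate metrics + dice table.

    Returns the confusion counts, the metric report, and mean +/- SD dice
    per finding class against the phantom truths.
    """
    config = config or PipelineConfig()
    chosen = [s for s in subjects if s.split == split]
    if not chosen:
        raise ValueError(f"no subjects in split {split!r}")
    counts = ConfusionCounts()
    dice_rows: list[dict] = []
    per_subject: list[dict] = []
    for s in chosen:
        report = run_end_to_end(
            s.oct_scan, s.fundus_scan, bundle, config,
            expected_modalities=("oct", "fundus"),
        )
        counts.update(s.label, report["final"])
        oct_f: OCTFindings = report["oct_findings"]
        fun_f: FundusFindings = report["fundus_findings"]
        if s.oct_truth.fluid is not None:
            dice_rows.append({"subject": s.subject_id, "finding": "fluid",
                              "dice": dice(oct_f.fluid, s.oct_truth.fluid)})
        if s.fundus_truth.vessels is not None:
            dice_rows.append({"subject": s.subject_id, "finding": "vessels",
                              "dice": dice(fun_f.vessels, s.fundus_truth.vessels)})
        if s.fundus_truth.exudates is not None:
            dice_rows.append({"subject": s.subject_id, "finding": "exudates",
                              "dice": dice(fun_f.exudates, s.fundus_truth.exudates)})
        per_subject.append({"subject": s.subject_id, "label": s.label,
                            "final": report["final"], "votes": report["votes"],
                            "csme_grade": report["csme_grade"]})
    metrics = classification_metrics(counts)
    summary: dict[str, tuple[float, float]] = {}
    for finding in ("fluid", "vessels", "exudates"):
        vals = [r["dice"] for r in dice_rows if r["finding"] == finding]
        if vals:
            summary[finding] = (float(np.mean(vals)), float(np.std(vals)))
    return {
        "counts": counts,
        "metrics": metrics,
        "dice_rows": dice_rows,
        "dice_summary": summary,
        "per_subject": per_subject,
    }
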