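"""Train the CNNs and the hybrid ensemble on a small cohort, then grade a subject.

Uses a 24-subject phantom cohort (one OCT + one fundus scan each) at a
reduced 64-px CNN input so the example runs in a couple of minutes. The final
label is the majority vote of the ANN, SVM and naive-Bayes classifiers
over the fused 16-D CNN feature vector.
"""

from retfuse.pipeline import evaluate_cohort, run_end_to_end, train_models
from retfuse.synthetic import generate_cohort

manifest, subjects = generate_cohort(24, prevalence=0.5, seed=7)
bundle, logs = train_models(subjects, seed=7, input_size=64,
                            feature_epochs=20, modality_epochs=4)
print(f"feature-CNN final training-batch accuracy: "
      f"{logs['features'].final_training_accuracy:.2f}")

res = evaluate_cohort(subjects, bundle, split="validation")
m = res["metrics"]
print(f"validation: accuracy {m.accuracy:.2f}, SE {m.sensitivity}, SP {m.specificity}")
print("dice vs truth:", {k: round(v[0], 3) for k, v in res["dice_summary"].items()})

subject = subjects[0]
report = run_end_to_end(subject.oct_scan, subject.fundus_scan, bundle,
                        expected_modalities=("oct", "fundus"))
print(f"subject {subject.subject_id}: true label {subject.label}, "
      f"votes {report['votes']}, final {report['final']}, CSME {report['csme_grade']}")
# The votes show each classifier's opinion; the final label needs at
# least two agreeing votes.
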