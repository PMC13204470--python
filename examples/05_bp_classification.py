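"""Three-class blood-pressure classification on the synthetic dataset.

Generates sessions with planted class effects (AO amplitude tracks the
SBP class, heart rate tracks the DBP class), runs the full measurement
and feature chain, and trains separate softmax models for SBP and DBP
with a stratified 30% held-out test set.
"""

from scgpipe.pipeline import bp_classification_experiment

result = bp_classification_experiment(n_sessions=120, seed=0)

print(f"windows retained by SQI screening: {result['n_retained']} "
      f"({result['n_excluded']} excluded)")
for target in ("sbp", "dbp"):
    print(f"\n{target.upper()} model — held-out accuracy "
          f"{result[f'{target}_accuracy']:.3f} on {result[f'{target}_n_test']} windows")
    print(f"confusion matrix (rows = true class 0/1/2):")
    print(result[f"{target}_confusion"])
    aucs = ", ".join(f"{k}: {v:.3f}" for k, v in result[f"{target}_auc"].items())
    print(f"one-vs-rest AUC — {aucs}")

# Classes follow the clinical bins (SBP: <120 / 120-135 / >135 mmHg;
# DBP: <80 / 80-85 / >85 mmHg). High accuracy here shows the pipeline
# recovers the generator's documented planted mapping — it says nothing
# about accuracy on real human recordings.
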