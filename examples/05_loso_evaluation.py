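"""Leave-one-subject-out evaluation on a small synthetic dataset.

Generates 4 subjects x 12 samples, preprocesses them, trains one model per
LOSO fold (short schedule for a quick demo) and prints pooled Acc/UAR/UF1.
Runs in about half a minute on one CPU.
"""

import pandas as pd

from dual_atme import (SynthConfig, TrainConfig, build_composite_manifest,
                       compute_features, evaluate_loso, generate_samples)

config = SynthConfig(n_subjects=4, samples_per_subject=12, displacement_px=3.0,
                     noise_sd=1.0, seed=7)
samples = generate_samples(config)
print(f"generated {len(samples)} samples from {config.n_subjects} subjects")

features = compute_features(samples)
records = pd.DataFrame([{"sample_id": s.sample_id, "subject_id": s.subject_id,
                         "source": s.source, "raw_label": s.raw_label}
                        for s in samples])
manifest, counts = build_composite_manifest(records)
print(counts.to_string(index=False))

report = evaluate_loso(TrainConfig(epochs=15, seed=0), manifest, features)
print("\npooled confusion matrix (rows = true, cols = predicted):")
print(report.pooled_confusion)
print(f"pooled Acc={report.pooled.acc:.3f} UAR={report.pooled.uar:.3f} "
      f"UF1={report.pooled.uf1:.3f}  (chance UAR = 0.333)")
print("\nUAR/UF1 are macro averages, robust to the Negative-heavy imbalance;")
print("well above 0.333 means the network recovers the class-specific motion.")
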