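"""Predict progression from raw channel images vs cell frequencies.

Builds a 40-core cohort in which progressing cores differ from
non-progressing ones only in spatial arrangement (cell-type frequencies
are class-matched), then runs the prediction framework -- per-channel
embeddings (download-free 'testhash' backbone), mini-batch sparse PCA
to 9 components, RBF-SVM with random oversampling under patient-grouped
5-fold cross-validation -- on both feature sources.
"""

import numpy as np

import imctme as it

cohort = it.generate_spatial_signal_cohort(n_cores=40, n_positive=12, seed=2)
y = cohort.labels
print(f"{len(y)} cores; baseline (modal-class) score = {it.baseline_score(y):.3f}")

emb = it.channel_embeddings(cohort.stacks, "testhash")
X_raw = it.features_from_subset(emb, list(emb))
rep_raw = it.train_eval(X_raw, y, groups=cohort.patients, seed=0, source="raw")
print(f"raw-channel source:   accuracy {rep_raw.mean_accuracy:.3f} "
      f"(folds {np.round(rep_raw.fold_accuracies, 2)})")

types = sorted(cohort.truths[0].df["lineage"].unique())
X_freq = np.array(
    [[t.df["lineage"].value_counts(normalize=True).get(tt, 0.0) for tt in types]
     for t in cohort.truths]
)
rep_freq = it.train_eval(X_freq, y, groups=cohort.patients, seed=0,
                         n_components=len(types), source="freq")
print(f"cell-frequency source: accuracy {rep_freq.mean_accuracy:.3f}")
print("\nthe spatial arrangement carries the outcome signal, so the raw-"
      "\nchannel source should far exceed both the frequency source and baseline.")

ranking = it.rank_markers(None, y, None, embeddings=emb, seed=0)
print("\nper-marker predictive ranking (accuracy of each channel alone):")
print(ranking[["marker", "mean_accuracy"]].round(3).to_string(index=False))
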