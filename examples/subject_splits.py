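"""Subject-wise evaluation protocol on a synthetic cohort.

10% of subjects form a fixed held-out test set; the rest are dealt into
10 cross-validation folds.  No patient ever appears in two subsets of the
same fold, so recordings from one person cannot leak between train,
validation and test.
"""

from pcgvit import SynthConfig, generate_dataset, make_splits

records = generate_dataset(SynthConfig(n_subjects=22, records_per_subject=3,
                                       duration_range=(5, 8), seed=0))
plan = make_splits(records, test_frac=0.1, n_folds=10, seed=0)

print(f"{len(records)} recordings from {len({r.subject_id for r in records})} subjects")
print(f"test subjects ({len(plan.test_subjects)}):", sorted(plan.test_subjects))
for i, (train_s, val_s) in enumerate(plan.folds):
    overlap = (train_s & val_s) | (train_s & plan.test_subjects) | (val_s & plan.test_subjects)
    print(f"fold {i}: {len(train_s)} train / {len(val_s)} val subjects, "
          f"leakage: {sorted(overlap) or 'none'}")
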