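"""Train and evaluate the classifier on a small synthetic cohort.

A scaled-down version of the full experiment: 16 subjects, 2-fold
subject-wise cross-validation, up to 25 epochs.  Prints per-fold held-out
metrics and the mean/sd summary.  Expect a few minutes on one CPU, and
noisy per-fold numbers at this cohort size (the acceptance benchmark uses
40 subjects and 60 epochs).  The fusion ablation sweep works the same way
with ``fusion_modes=("attention", "average", "min", "max", "concat")``.
"""

from pcgvit import SynthConfig, TrainConfig, generate_dataset, run_experiment, summarize_experiment

records = generate_dataset(SynthConfig(n_subjects=16, records_per_subject=2,
                                       duration_range=(5.0, 10.0),
                                       murmur_snr_db=10.0, seed=3))
results = run_experiment(
    records,
    train_cfg=TrainConfig(max_epochs=25, patience=10, seed=3),
    fusion_modes=("attention",),
    n_folds=2, split_seed=3)

print(results[["fusion_mode", "fold", "epochs_run", "accuracy",
               "sensitivity", "specificity", "f1", "score"]].to_string(index=False))
print()
print(summarize_experiment(results).round(3).to_string())
# accuracy/sensitivity/specificity/f1/score are fractions on the held-out
# test subjects; "score" is the mean of sensitivity and specificity.
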