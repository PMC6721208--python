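"""Stratified cross-validated prediction accuracy on a synthetic cohort.

Within each training fold the detector pool (including its data-driven
thresholds) is rebuilt from the training subjects only; held-out subjects
are scored with both the point-estimate rule set and the posterior-ensemble
average, and predictions are pooled into a single F1 at threshold 0.5.
"""

from cladetime import (
    FilterParams, PoolParams, PriorConfig, SimConfig,
    build_cohort, cross_validate, generate_cohort,
)

sc = generate_cohort(SimConfig(n_subjects=16, n_timepoints=12, n_otus=30,
                               n_reads=10_000, seed=3))
cohort = build_cohort(sc.counts, sc.sample_map, sc.subjects, sc.tree,
                      FilterParams(n_counts_sample=1000, n_s=1))
result = cross_validate(cohort, PriorConfig(),
                        PoolParams(n_w=6, t_max=cohort.duration / 2),
                        n_folds=4, seed=0, n_samples=3000)
print(f"F1 (point estimate):  {result.f1_point:.3f}")
print(f"F1 (ensemble):        {result.f1_ensemble:.3f}")
print(f"F1 (majority class):  {result.f1_majority_baseline:.3f}")
print()
print("Values above the majority-class baseline indicate that the learned")
print("rules carry real out-of-sample information about case status.")
print(result.to_frame().head(8).to_string(index=False))
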