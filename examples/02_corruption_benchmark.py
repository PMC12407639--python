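"""Dropout-recovery benchmark: how well are deliberately removed counts restored?

Zeroes 20% of the non-zero entries of a synthetic complete matrix, imputes the
corrupted matrix, and scores recovery on the logged scale.  The masked MSE of
the imputed matrix should fall well below the zero-filled (non-imputed)
baseline, and the identification rate reports the fraction of removed counts
restored to non-zero values.
"""

from mbsparse import (
    PipelineConfig,
    SyntheticSpec,
    inject_dropout,
    recovery_report,
    run_mbsparse,
    synthesize_count_matrix,
)

spec = SyntheticSpec(n_samples=80, n_taxa=150, zero_inflation=0.25, seed=11)
complete = synthesize_count_matrix(spec)
experiment = inject_dropout(complete, rate=0.2, seed=12)
print(f"removed {len(experiment.injected_mask)} non-zero entries "
      f"({experiment.rate:.0%} of non-zeros)")

result = run_mbsparse(experiment.corrupted, PipelineConfig(seed=13))
report = recovery_report(experiment, result)

print(f"masked MSE  imputed:     {report.mse:.4f}")
print(f"masked MSE  non-imputed: {report.baseline_mse:.4f}   (zeros left in place)")
print(f"identification rate:     {report.identification_rate:.1%} of removed counts restored")
print(f"mean per-taxon Pearson   imputed {report.mean_pearson:.4f} / "
      f"non-imputed {report.baseline_mean_pearson:.4f}")
# The MSE gap is the headline: neighborhood-informed fills land far closer to
# the true removed counts than leaving zeros in place.
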