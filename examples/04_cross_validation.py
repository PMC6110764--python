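"""Five-fold cross-validation of the full pipeline on synthetic data.

Generates a balanced interaction dataset with strong class separation and
reports per-fold accuracy, sensitivity, precision, MCC and AUC, plus the
mean +/- standard deviation aggregation.
"""

from rotpssm import (
    PipelineConfig,
    SyntheticConfig,
    TwoDPCAConfig,
    five_fold_cv,
    generate_dataset,
)

dataset = generate_dataset(
    SyntheticConfig(n_proteins=60, n_pairs_per_class=60,
                    length_range=(40, 100), separation=3.0, seed=7)
)
config = PipelineConfig(twodpca=TwoDPCAConfig(d=10), K=10, L=2)
report = five_fold_cv(dataset, config, seed=7)
print(report.to_text())
# Each row is one held-out fold; "Average" aggregates the five folds.
# With separation 3 the latent clusters are well apart, so all metrics
# sit at or near 100%.
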